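import textwrap

import pytest

from osteoconcord.simulate import CohortConfig, generate_cohort

SAM_TEXT = textwrap.dedent("""\
    @HD\tVN:1.6\tSO:unsorted
    @SQ\tSN:chrX\tLN:156040895
    @SQ\tSN:chrY\tLN:57227415
    y1\t0\tchrY\t100\t40\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII
    y2\t0\tchrY\t200\t40\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII
    y3\t0\tchrY\t300\t37\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII
    ylow\t0\tchrY\t400\t10\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII
    ysec\t256\tchrY\t500\t40\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII
    x1\t0\tchrX\t100\t40\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII
    x2\t0\tchrX\t200\t33\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII
    u1\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII
    """)


@pytest.fixture
def sam_file(tmp_path):
    path = tmp_path / "sample.sam"
    path.write_text(SAM_TEXT)
    return path


@pytest.fixture(scope="session")
def default_cohort():
    """A default-parameter synthetic cohort, shared across tests."""
    return generate_cohort(CohortConfig(seed=20260923))


def separable_config(seed: int, n: int, accuracy: float = 1.0,
                     trait: str = "sciatic_notch") -> CohortConfig:
    """Single-trait cohort where each sex scores its own extreme with
    probability `accuracy` and the opposite extreme otherwise."""
    a = accuracy
    return CohortConfig(
        seed=seed,
        n_individuals=n,
        trait_distributions={
            trait: {"F": [a, 0, 0, 0, 1 - a], "M": [1 - a, 0, 0, 0, a]},
        },
        missingness={trait: 0.0},
    )
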