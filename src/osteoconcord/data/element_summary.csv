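element,sex,n_correct,n_indeterminate,n_incorrect
combined,pooled,45,1,1
combined,female,15,1,1
combined,male,29,0,0
os_coxae,pooled,45,2,2
os_coxae,female,16,1,2
os_coxae,male,28,1,0
skull,pooled,46,8,6
skull,female,15,2,5
skull,male,31,6,1
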