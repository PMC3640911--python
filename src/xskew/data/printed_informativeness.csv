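# Published CAG-STR heterozygosity (informative k out of n recruited).
group,k,n
controls,356,401
patients,134,143
combined,490,544
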