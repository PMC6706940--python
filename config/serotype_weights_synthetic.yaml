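# Synthetic placeholder serotype weights (NOT the published values).
# Replace with the published DR3/DR4-DQ8 group weights before use on real data.
DR3/DR4-DQ8: 3.9
DR4-DQ8/DR4-DQ8: 3.6
DR3/DR3: 3.3
DR4-DQ8/X: 2.3
DR3/X: 2.2
X/X: 0.0
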