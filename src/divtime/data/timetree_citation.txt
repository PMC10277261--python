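Kumar S, Suleski M, Craig JM, Kasprowicz AE, Sanderford M, Li M, Stecher G, Hedges SB (2022)
TimeTree 5: an expanded resource for species divergence times.
Molecular Biology and Evolution 39(8): msac174. https://doi.org/10.1093/molbev/msac174
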