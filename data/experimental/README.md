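# Experimental cross-link tables (user-supplied)

The acceptance tests that reproduce published Sigma-L values and the horse
myoglobin violation census need the published experimental cross-link
lists (supplementary material of the original benchmark publications), plus
the myoglobin crystal structure. Neither is redistributed with this package.

To enable those tests, place here:

- `2v1h_crosslinks.tsv` — the 20 experimental horse-myoglobin cross-links
- `1ao6_repeat2_crosslinks.tsv`, `1ao6_repeat6_crosslinks.tsv` — the
  serum-albumin repeat-2 and repeat-6 cross-links (disulfides excluded)
- `2v1h.pdb` — the myoglobin structure (`https://www.rcsb.org/structure/2V1H`)

Cross-link TSV format (tab-separated, header required, author numbering):

    protein	res_i	res_j	reagent	confidence
    2V1H	34	42	ABAS	1.0

`confidence` is optional (defaults to 1.0); `reagent` must be one of
ABAS, TATA, SDA, DSA, DSG, BS3, SS.
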