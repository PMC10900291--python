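# Synthetic benchmark cross-link tables (user-supplied)

The acceptance test for per-protein maximum topological lengths needs the
synthetic cross-link lists of the benchmark proteins (published
supplementary material; not redistributed).

Expected files: `1tig_crosslinks.tsv`, `1k40_crosslinks.tsv`,
`1koy_crosslinks.tsv`, `1hre_crosslinks.tsv`, in the cross-link TSV format
described in `../experimental/README.md`.
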