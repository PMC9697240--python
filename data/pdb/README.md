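# Experimental reference structures

The homo-step regression in `tests/test_acceptance.py` analyses three
experimentally determined B-DNA duplexes that cannot be redistributed with
the package. To run it, download them here:

    curl -o 1kbd.pdb https://files.rcsb.org/download/1KBD.pdb
    curl -o 1fzx.pdb https://files.rcsb.org/download/1FZX.pdb
    curl -o 1d89.pdb https://files.rcsb.org/download/1D89.pdb

- **1KBD** — ds-5'-CTGGGGACTTTCCAGG-3', NMR
- **1FZX** — ds-5'-GGCAAAAAACGG-3', NMR
- **1D89** — ds-5'-CGCGAAAAAACG-3', X-ray

Without these files the regression test reports a failure explaining what is
missing; everything else in the suite is self-contained.
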