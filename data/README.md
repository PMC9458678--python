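# External reference data

Files expected here by the crystal-structure and experimental-curve
acceptance tests (not redistributed with the package):

- `5EDV.pdb` — HOIP RBR / UbcH5B~Ub complex, from
  https://files.rcsb.org/download/5EDV.pdb
- `4LJP.pdb` — HOIP RING2-LDD, from
  https://files.rcsb.org/download/4LJP.pdb
- `hoip_rbr_sec_saxs.dat` — the published HOIP RBR SEC-SAXS curve
  (3-column q / I / sigma text), from the authors' data deposit.

Without these files the corresponding tests in
`tests/test_acceptance.py` report failure with an explanatory message;
all other tests are self-contained.
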