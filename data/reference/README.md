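# Reference structures

This directory holds stripped local copies of the five Sso7d reference
entries (PDB 1BF4, 1BNZ, 1C8C, 1JIC, 1SSO) used by the five-structure
backbone-RMSD check. Populate it once with

```bash
python scripts/fetch_reference_structures.py
```

(network required). The test suite and `scripts/acceptance.py` skip or
omit that check when the files are absent; everything else works without
them.
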