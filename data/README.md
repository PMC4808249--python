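# data/

Optional inputs for the case-study tests and acceptance target.

This environment has no route to the PDB archive, so the coordinate files
cannot be vendored here. To enable the case-study checks, place PDB-format
files (e.g. from https://files.rcsb.org/download/1G7R.pdb) at:

- `data/1G7R.pdb` — before-binding structure (free IF2/eIF5B); enables the
  longest-disordered-region criterion and acceptance target t8.
- `data/1G7T.pdb` — after-binding structure (GDPNP complex); additionally
  enables the soft CCP-peak check.
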