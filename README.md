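# ccprofile

Per-residue conformational change profiling of protein structure pairs.

Given two PDB-format coordinate files of the same protein — one before and
one after binding — `ccprofile` maps both chains onto a common reference
sequence and computes a set of position-aligned tracks:

- **ccp** — conformational change profile: a 21-residue window slides along
  the reference; at each position the C-alpha coordinates observed in both
  structures are rigidly superposed (iteratively reweighted or plain least
  squares) and the unweighted RMSD is the profile value. Positions lacking
  coordinates in either structure are null.
- **binding_flag / binding_names** — residues with any heavy atom within
  5 Å of a binding-target heavy atom are flagged; target names attach within
  3 Å. Binding targets are the molecules present in the after-binding file
  but absent from the before-binding file (waters and pseudo-ligands such as
  selenomethionine excluded; targets are categorized as protein, nucleic
  acid, ligand or ion).
- **ss_before / ss_after** — secondary structure from backbone hydrogen-bond
  patterns (eight classes merged to H/E/C) with two overlay classes:
  D (in SEQRES, no coordinates) and N (in the reference, outside SEQRES).
  Classic `.dssp` files can be ingested instead of the internal assigner.
- **conservation** — entropy of independent-count-weighted amino-acid
  frequencies per alignment column, normalized from [−ln 20, 0] to [0, 1]
  (requires a user-supplied aligned-FASTA MSA).
- **hydropathy** — 15-residue Kyte–Doolittle window sums over the reference.
- user annotation tracks (domains, phosphosites, catalytic sites, …) from a
  simple interval TSV.

Structure pairing follows strict rules: fragments must embed into the
reference gaplessly end-to-end with identity ≥ 95% and e-value < 0.001, the
two mapped intervals must overlap, and the after-file's molecular inventory
must strictly contain the before-file's.

## Command line

Enumerate valid before/after pairs in a directory of PDB files:

```bash
ccprofile pair --pdb-dir structures/ --ref ref.fasta --out pairs.tsv
```

Compute the full profile set for one pair:

```bash
ccprofile profile \
    --before free.pdb --before-chain A \
    --after bound.pdb --after-chain A \
    --ref ref.fasta [--msa msa.fasta] [--annotations ann.tsv] \
    [--window 21] [--site-cutoff 5.0] [--name-cutoff 3.0] \
    [--estimator reweighted|least_squares] [--config conf.ini] \
    --out prefix
```

This writes `prefix.tsv` (wide per-position table, nulls as `NA`),
`prefix.json` (same data with native nulls), `prefix.meta.txt` (pair
metadata: global RMSD, worse resolution, pH/temperature, loop fractions,
binding targets) and `prefix.superposed.pdb` (MODEL 1 = before, MODEL 2 =
after transformed into the before frame). A `key=value` config file can
override any defaulted option; per-stage timings are logged to stderr.

Annotation TSV format: `track<TAB>start<TAB>end[<TAB>label]`, 1-based closed
intervals on reference positions.

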