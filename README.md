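# relkit

A self-contained pipeline for defining a relaxase protein family from a
single seed sequence, and for characterizing its origin-of-transfer (oriT)
region:

1. **homology_search** — iterative position-specific score matrix (PSSM)
   search with empirically calibrated Gumbel E-values (psi-blast style,
   full dynamic programming, desk scale).
2. **clustering** — greedy centroid clustering (exact dedup at 100 %
   identity; 50 %-identity centroids before motif discovery).
3. **motifs** — ZOOPS expectation-maximization signature discovery with an
   empirical (shuffled-input, Gumbel-fitted) significance null, exact
   PWM-scan p-values, cross-family occurrence tables, sequence-logo
   information content and conservation shading.
4. **phylogeny** — center-star alignment, p/Poisson distances,
   neighbor-joining with bootstrap supports, condensed trees, and a
   two-clade leaf partition.
5. **plasmid_assignment** — six-frame translated matching against circular
   plasmids (identity > 0.95 over coverage > 0.80) and a clade x
   plasmid-location crosstab.
6. **dna_features** — dinucleotide wedge-model DNA curvature (two bundled
   parameter sets), 600-bp smoothed z-profiles with peak calling, direct /
   inverted repeat and palindrome discovery, GC windows, and nick-site
   localization from the 14-mer recognition sequence.
7. **hydrodynamics** — Svedberg molar mass and frictional ratio with
   bundled residue partial-specific-volume and buffer-density tables.
8. **synthetic_data** — seeded generators for two-clade protein families
   with planted PWM signatures, decoy sets, and circular plasmids with
   embedded CDSs, phased-A-tract bent regions and an oriT cassette; every
   generator emits a ground-truth manifest used by the recovery tests.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion.  Two
of them require real-sequence inputs (accession NC_015148.1 and the
published member list) that cannot be fetched in an offline environment;
they fail with an explanatory message unless plain-text copies are placed
under `data/external/` (see `data/external/README.md`).

## CLI

```sh
relkit simulate -o fixture --seed 3              # synthetic data + manifest
relkit run-all --seed-protein fixture/seed.fasta \
    --protein-db fixture/database.fasta \
    --plasmid-db fixture/plasmids.fasta \
    --seed 3 -o out                              # full pipeline bundle
relkit search seed.fasta db.fasta                # single stages ...
relkit cluster members.fasta --threshold 0.5
relkit motifs centroids.fasta
relkit tree members.fasta --bootstrap 1000
relkit curvature plasmids.fasta --params AAWedge
relkit locate plasmids.fasta
```

`run-all` writes members.tsv/.fasta, clusters.tsv, signatures.meme,
occurrence.tsv, tree.nwk, clades.tsv, localization.tsv, crosstab.tsv,
curvature wiggle/BED files, features.gff3 and run.json (the config echo
that makes the bundle reproducible bit-for-bit given the same seed).

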