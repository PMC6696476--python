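# hnox-scout

Motif-based discovery of candidate nitric-oxide-binding proteins, plus the
UV/Vis spectral analysis used to validate them.

Proteins that sense NO through a heme cofactor — H-NOX (Heme Nitric
Oxide/Oxygen binding) domains and the reduced "H-NOX centers" found in
complex plant proteins — share a small set of functionally critical
residues at the heme-binding pocket rather than overall sequence
similarity, so they routinely escape BLAST-style homology searches.
`hnox-scout` implements the alternative: a *search term* of fixed residues
separated by bounded wildcard gaps, e.g.

```
Hx(12)Px(14,16)YxSxR
```

(a histidine, exactly 12 arbitrary residues, a proline, 14–16 arbitrary
residues, then the YxSxR signature), applied exhaustively to a proteome.
The package covers the full loop:

* **`motif`** — parse/format the flexible-gap dialect, span algebra, and
  *relaxation*: dropping an interior fixed residue (e.g. the proline,
  giving `Hx(27,29)YxSxR`) merges the surrounding gaps by summing bounds
  and provably widens the matched language while preserving span bounds.
* **`builder`** — extract a motif from an alignment of functional centers
  with annotated critical columns (fixed tokens = unanimous critical
  columns; gap bounds = min/max non-gap counts between them).
* **`scan`** — enumerate every match *realization* (start + gap-length
  vector) on FASTA proteomes, map key residues to 1-based positions,
  list residues (e.g. cysteines) inside a matched span, and collapse
  gene-model hits (`At4g01160.1/.2`) to loci.
* **`spectra`** — detect Soret/β/α bands in UV/Vis spectra and classify
  heme states by canonical Soret positions (408 nm ferric His-ligated;
  418 nm + β 525/α 553 nm ferrous 6-coordinate; 398 nm 5-coordinate
  nitrosyl; 436 nm free hemin; no Soret = apo), plus NO-donor titration
  saturation analysis and post-saturation dissociation monitoring.
* **`synth`** — seeded generators for proteomes with planted motif
  instances (exact ground truth), state-templated spectra, binding
  isotherm titrations and first-order dissociation series.
* **`hnox-scout` CLI** — `scan`, `build-motif`, `relax`,
  `classify-spectrum`, `titration`, `simulate`, `run`.

## Worked example

Build a synthetic proteome carrying 4 strict instances and 30
relaxed-only instances at recorded positions (the `avoid` list forces
those 30 to escape the strict term):

```python
from hnox_scout import synth
from hnox_scout.motif import parse_motif, relax_letter

strict = parse_motif("Hx(12)Px(14,16)YxSxR")
relaxed = relax_letter(strict, "P")          # Hx(27,29)YxSxR
truth = synth.gen_proteome(
    60, 400,
    [synth.PlantSpec(strict, 4), synth.PlantSpec(relaxed, 30, avoid=(strict,))],
    seed=11,
)
synth.write_proteome(truth, "proteome.fasta", "truth.json")
```

then scan it with both terms:

```bash
hnox-scout relax --motif "Hx(12)Px(14,16)YxSxR" --residue P
# Hx(27,29)YxSxR
hnox-scout scan --motif "Hx(12)Px(14,16)YxSxR" --fasta proteome.fasta --out strict.tsv
# 4 matching records, 4 realizations
hnox-scout scan --motif "Hx(27,29)YxSxR" --fasta proteome.fasta --out relaxed.tsv
# 34 matching records, 34 realizations
```

Or run the whole workflow from a config:

```python
from hnox_scout import RunConfig, run_discovery
report = run_discovery(RunConfig.from_dict({
    "motif": {"text": "Hx(12)Px(14,16)YxSxR"},
    "relax": ["P"],
    "fasta": ["proteome.fasta"],
    "out_dir": "out",
}))
print(report["motifs"])
```

On the synthetic proteome above this prints:

```
{'base':      {'motif': 'Hx(12)Px(14,16)YxSxR', 'n_matching_records': 4,
               'n_realizations': 4,  'n_loci': 4},
 'relaxed_P': {'motif': 'Hx(27,29)YxSxR',       'n_matching_records': 34,
               'n_realizations': 34, 'n_loci': 34}}
```

i.e. the strict term finds exactly the 4 strict plants, and omitting the
proline widens the candidate set to 34 matching gene models — the
strict-to-relaxed widening behaviour the search strategy is built around.
Match tables (`matches_*.tsv`) carry, per realization, the 1-based span,
the realized gap lengths, and the key-residue map (for a strict-motif
match anchored at histidine 357 with maximal gaps: `H1=357; P1=370;
Y1=387; S1=389; R1=391`).

Spectral validation of a candidate:

```bash
hnox-scout simulate spectrum --state FERRIC_HIS_LIGATED --seed 3 --out ferric.csv
hnox-scout classify-spectrum --in ferric.csv
# {"state": "FERRIC_HIS_LIGATED",
#  "rationale": "Soret at 408.1 nm within 408±4 (His-ligated ferric)"}
```

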