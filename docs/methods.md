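# Methods

## Flexible-gap motifs

A motif is an ordered token list: FIXED tokens carry one of the 20
standard amino-acid letters (implicit length 1); GAP tokens carry
inclusive length bounds `1 ≤ min ≤ max`, written `x`, `x(n)` or
`x(n,m)`.  Motifs are *anchored* — the first and last tokens are FIXED —
so every match has a well-defined residue span, and the span of any match
lies in `[Σ min, Σ max]` over tokens.  Canonical form merges adjacent
gaps by summing both bounds; parsing canonicalizes, and
`parse(format(m)) = m` on canonical motifs.

**Relaxation** replaces an interior fixed token by `gap(1,1)` and merges
it with its neighbours.  Because a fixed residue is a special case of a
length-1 wildcard, the relaxed motif's language contains the original's;
gap merging conserves the summed bounds, so span bounds are invariant.
Both properties are verified in the suite — the language containment by
exhaustive enumeration of the inner motif's language (every gap-letter
assignment over a small alphabet) under an explicit combinatorial budget
that refuses rather than truncates.  Enumerating the inner language
rather than all strings of bounded length gives the same verdict
(non-matching strings cannot witness a violation) at exponentially lower
cost.

The dialect deliberately excludes PROSITE character classes (`[...]`,
`{...}`): the search terms this package exists for use only fixed letters
and bounded gaps, and the grammar is extensible if classes are ever
needed.  Non-standard residue codes (B, Z, X, U, O) are rejected at fixed
positions and match only gap positions during scanning — conservative,
so a reported key residue is always literally present.

## Scanning semantics

Coordinates are 1-based inclusive, mirroring protein residue numbering
(`H357`).  A *match realization* is a (start, gap-length vector) pair
under which every fixed token equals the sequence letter.  The default
`ALL_REALIZATIONS` policy reports every realization ordered by (start,
end, gap vector); `LEFTMOST_SHORTEST_PER_ANCHOR` keeps the
lexicographically smallest gap vector per anchor.  Candidate counting
uses distinct matching sequence IDs, so realization multiplicity never
inflates protein counts; a further aggregation collapses AGI gene-model
suffixes (`At4g01160.1/.2 → AT4G01160`) while non-AGI IDs group
verbatim.  `*` is a hard segment break (no match crosses it); `-` and
`.` are stripped on input with a warning.

The scanner is validated against an independent brute-force oracle that
flat-enumerates every (start, gap-vector) combination with plain offset
arithmetic, over 1000+ seeded random sequences spanning alphabet sizes
4–20, plus a hit-dense regime using a motif-letter-enriched alphabet.

## Motif extraction from center alignments

Critical columns are *user-supplied functional annotation*, not inferred
conservation: the residues known to accommodate the heme (H, P, and the
YxSxR signature) are marked, must be unanimous and gap-free across rows,
and become FIXED tokens.  Each inter-column stretch becomes a gap token
bounded by the min/max count of non-gap characters any row places there;
a zero-count row is an error because anchored gap semantics require
`min ≥ 1`.  The reconstruction property (building an alignment from a
motif's extreme realizations and re-extracting it returns the motif) is
tested for both search terms.

## Spectral model and classifier

Synthetic spectra are sums of Gaussian bands on a 350–600 nm grid (1 nm
default) over a linear baseline, with seeded i.i.d. Gaussian noise.
Band lineshape is a modelling choice — classification uses only peak
positions, so any symmetric unimodal lineshape would serve.  Built-in
state templates use the canonical centers:

| state               | bands (nm, σ nm, AU)                         |
|---------------------|----------------------------------------------|
| ferric, His-ligated | Soret 408 (12, 0.50); broad 530 (22, 0.05)   |
| ferrous 6c          | Soret 418 (12, 0.50); β 525, α 553 (7, 0.08) |
| ferrous 5c-NO       | Soret 398 (14, 0.45)                         |
| free hemin          | Soret 436 (10, 0.40); shoulder 400 (22, 0.18)|
| apo                 | none                                         |

The broad ~530 nm ferric feature is generated but *not required* by the
classifier, since it is a weak and variably reported feature.

Classification pipeline: a linear baseline is estimated on the flat
570–600 nm tail and removed; Savitzky–Golay smoothing (window 11,
order 2); local maxima above a prominence threshold of 0.04 AU; apex
positions refined by a least-squares parabola over a ±9-point window
(the windowed generalization of 3-point parabolic interpolation —
unbiased for symmetric bands and far less sensitive to apex noise on
broad Soret bands).  The prominence threshold separates the
smoothed-noise floor (max excursions ≈ 0.02 AU at noise sd 0.01) from
the weakest genuine bands (β/α at ≈ 0.08 AU) with a factor-of-two margin
on both sides.

State rules are ordered and window-based (defaults ±4–6 nm around the
centers above, configurable), applied to the most prominent Soret call:
no Soret → apo; 436±5 → free hemin; 418±4 *and* β 525±6 *and* α 553±6 →
ferrous 6c; 398±4 → 5c nitrosyl; 408±4 → ferric; otherwise AMBIGUOUS
listing the nearest candidate states.  Ferrous-6c is tested before the
5c/ferric windows so the α/β requirement disambiguates 418 nm from
nearby shoulders.  The transient 6-coordinate NO intermediate (~420 nm)
is not a built-in state — it is generally not observable on plate-reader
mixing timescales — but custom windows can represent it.

## Titration and dissociation

A titration series holds spectra at non-decreasing NO-donor
concentrations.  Saturation is operational, not thermodynamic: the
saturation index is the smallest step after which every *consecutive*
max-norm spectral change stays below the user tolerance (default
0.005 AU), and the series is saturated only if that holds through the
final step.  Consecutive (not all-pairs) differences define the
criterion; this matches the closed-form oracle used in the tests, where
the synthetic isotherm `f = c/(K_app + c)` predicts each increment as
`Δf · max|A_bound − A_free|`.  The analysis is invariant to uniform
scaling of absorbance and tolerance together.  Synthetic wild-type
vs. mutant comparisons (mutant `K_app` = 2× wild type) reproduce the
expected ordering: the mutant saturates at an equal or higher donor
concentration.

Dissociation analysis is purely spectral-state detection over time — no
kinetic fitting.  The generator mixes 5c-nitrosyl and ferric end-state
curves with ferric fraction `1 − exp(−k t)`; the analyzer reports the
first time point whose spectrum classifies as His-ligated ferric.  The
test oracle computes the clean mixture's argmax on a dense grid and
finds the first time it enters the ferric window, independent of the
package's peak detector.

## Synthetic proteomes

Background residues are i.i.d. with configurable frequencies (uniform
default; an approximate Arabidopsis composition table is shipped).
Planted instances sample a gap vector uniformly from the motif's bounds,
write the fixed letters, and fill gaps from the background model.  In
*exclusive* mode a record is re-rolled until every watched-motif match
lies inside a planted span, so ground truth is exact (100% precision and
recall by construction); *permissive* mode allows chance hits and is
used for calibration against the closed-form expectation

```
E[hits] = Σ_g (L − span(g) + 1)⁺ · Π_fixed freq(residue)
```

(for `Hx(27,29)YxSxR` on 10,000 uniform residues: (9968+9967+9966)/20⁴ ≈
0.1869 realizations).  Monte-Carlo counts over 200 seeded random
1000-mers agree within 3 Poisson sigma.  Isoform duplication emits a
`.2` gene model sharing the sequence (and hence the planted region) of
its `.1` sibling, exercising locus collapsing.

## Problem sizes and numerical choices

The suite runs the scanner-oracle comparison on 1100 sequences of length
≤ 60, the calibration on 200 × 1000-mers, and the noisy-classification
check on 500 draws at sd 0.01 AU — sizes at which the statistical
assertions (3σ bands, ≥95% accuracy) are already stable across seeds
while the whole suite stays interactive (a few seconds).  Determinism:
scanning involves no randomness and all generators take explicit seeds,
so identical configs byte-reproduce all output tables.  Degenerate
inputs are errors, not silent answers: empty FASTA records, inverted gap
bounds, unanchored motifs, spectra without 350–600 nm coverage,
titrations with fewer than 3 steps, and language enumerations over
budget all raise with the offending item named.

## Limitations

* The synthetic proteome model is i.i.d.; real proteomes have
  compositional autocorrelation, domain repeats and homologous families,
  so real-data hit counts will deviate from the closed-form expectation
  even when the scanner is exact.  Passing calibration shows scanner
  correctness, not biological specificity of a motif.
* Gaussian bands with fixed widths idealize real heme spectra
  (asymmetric lineshapes, instrument response, scattering baselines);
  the classifier's window logic transfers, but its measured accuracy
  under synthetic noise does not directly quantify accuracy on
  instrument data.
* Only peak positions drive state calls; extinction coefficients, redox
  thermodynamics and NO-dimer chemistry are out of scope.
* Motif matching is exact (no substitutions, no scoring); a single
  conservative substitution at a fixed position hides a true site, which
  is the intended trade-off of the search-term approach.
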