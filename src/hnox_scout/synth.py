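"""Seeded generators: planted-motif proteomes, state spectra, NO series.

Everything here provides ground truth for the pipeline: proteomes whose
motif instances are planted at recorded spans, spectra composed from
state-specific absorption bands with a linear baseline and Gaussian
noise, binding-isotherm titration series, and first-order dissociation
time courses.  All randomness flows from explicit integer seeds and the
same seed reproduces byte-identical output.

The background sequence model is i.i.d. with configurable residue
frequencies (uniform by default; an Arabidopsis-like table is shipped).
In *exclusive* planting mode the generator re-rolls any record whose
background accidentally creates a motif hit outside a planted span, so
planted spans are exactly the matches a scanner must report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import spectra as sp
from .motif import Motif, format_motif, parse_motif, realization_length, span_bounds
from .scan import ALL_REALIZATIONS, ProteinRecord, find_matches

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Approximate amino-acid composition of the A. thaliana proteome; an
# optional alternative to the uniform background model.
ARABIDOPSIS_AA_FREQS = {
    "A": 0.063, "C": 0.018, "D": 0.054, "E": 0.067, "F": 0.044,
    "G": 0.064, "H": 0.023, "I": 0.053, "K": 0.064, "L": 0.096,
    "M": 0.024, "N": 0.043, "P": 0.049, "Q": 0.035, "R": 0.055,
    "S": 0.091, "T": 0.051, "V": 0.069, "W": 0.012, "Y": 0.029,
}


class GenerationError(ValueError):
    """Impossible generator request."""


# ---------------------------------------------------------------------------
# planted proteomes

@dataclass(frozen=True)
class Plant:
    """Ground-truth record of one planted motif instance."""

    seq_id: str
    motif_text: str
    start: int  # 1-based inclusive
    end: int
    gap_lengths: tuple[int, ...]


@dataclass(frozen=True)
class PlantSpec:
    """Request to plant ``count`` instances of ``motif``.

    ``avoid`` lists motifs the planted fragment must NOT match — used to
    plant relaxed-only instances that escape the strict motif.
    """

    motif: Motif
    count: int
    avoid: tuple[Motif, ...] = ()


@dataclass
class PlantedProteomeTruth:
    records: list[ProteinRecord]
    plants: list[Plant]
    generator_params: dict


def _freq_arrays(freqs: dict[str, float] | None) -> tuple[list[str], np.ndarray]:
    if freqs is None:
        return list(AA20), np.full(20, 1 / 20)
    letters = sorted(freqs)
    p = np.array([freqs[a] for a in letters], dtype=float)
    if np.any(p < 0) or p.sum() <= 0:
        raise GenerationError("residue frequencies must be non-negative and sum > 0")
    return letters, p / p.sum()


def _random_seq(rng: np.random.Generator, n: int, letters, p) -> list[str]:
    return list(rng.choice(letters, size=n, p=p))


def _write_instance(
    rng: np.random.Generator, motif: Motif, letters, p
) -> tuple[str, tuple[int, ...]]:
    """Sample a gap vector uniformly from bounds and fill gaps from the background."""
    gaps = tuple(
        int(rng.integers(motif.tokens[i].min_len, motif.tokens[i].max_len + 1))
        for i in motif.gap_indices
    )
    out = []
    gi = 0
    for tok in motif.tokens:
        if tok.is_fixed:
            out.append(tok.residue)
        else:
            out.extend(_random_seq(rng, gaps[gi], letters, p))
            gi += 1
    return "".join(out), gaps


def gen_proteome(
    n_records: int,
    length: int,
    plants: Sequence[PlantSpec] = (),
    seed: int = 0,
    freqs: dict[str, float] | None = None,
    isoform_duplication: float = 0.0,
    exclusive: bool = True,
    max_retries: int = 200,
) -> PlantedProteomeTruth:
    """Generate a proteome of ``n_records`` i.i.d. sequences with planted motifs.

    Each planted instance is placed in its own record at a random position.
    IDs are AGI-style (``At<chr>g<5 digits>.1``); with probability
    ``isoform_duplication`` a planted record gains a ``.2`` isoform sharing
    the same sequence (hence the same planted region).  In exclusive mode
    any record whose scan result disagrees with its planted ground truth is
    re-rolled; in permissive mode chance extra hits are allowed.
    """
    if n_records < len([p for spec in plants for p in range(spec.count)]):
        raise GenerationError("more planted instances than records")
    rng = np.random.default_rng(seed)
    letters, p = _freq_arrays(freqs)
    watch: list[Motif] = []
    for spec in plants:
        for m in (spec.motif, *spec.avoid):
            if format_motif(m) not in {format_motif(w) for w in watch}:
                watch.append(m)

    assignments: list[PlantSpec | None] = [None] * n_records
    slot = 0
    for spec in plants:
        for _ in range(spec.count):
            assignments[slot] = spec
            slot += 1

    loci = rng.choice(np.arange(10_000, 90_000), size=n_records, replace=False)
    records: list[ProteinRecord] = []
    truth: list[Plant] = []
    for ri in range(n_records):
        chrom = int(rng.integers(1, 6))
        seq_id = f"At{chrom}g{int(loci[ri]):05d}.1"
        spec = assignments[ri]
        for attempt in range(max_retries):
            seq = _random_seq(rng, length, letters, p)
            plant: Plant | None = None
            if spec is not None:
                frag, gaps = _write_instance(rng, spec.motif, letters, p)
                if spec.avoid and any(
                    find_matches(m, ProteinRecord("f", "", frag)) for m in spec.avoid
                ):
                    continue  # fragment itself matches an avoided motif; re-roll
                if len(frag) > length:
                    raise GenerationError(
                        f"planted span ({len(frag)}) longer than sequence ({length})"
                    )
                start0 = int(rng.integers(0, length - len(frag) + 1))
                seq[start0 : start0 + len(frag)] = list(frag)
                plant = Plant(
                    seq_id, format_motif(spec.motif), start0 + 1, start0 + len(frag), gaps
                )
            rec = ProteinRecord(seq_id, "synthetic", "".join(seq))
            if exclusive and not _plant_is_exclusive(rec, plant, watch):
                continue
            records.append(rec)
            if plant is not None:
                truth.append(plant)
                if rng.random() < isoform_duplication:
                    iso_id = seq_id[:-2] + ".2"
                    records.append(ProteinRecord(iso_id, "synthetic isoform", rec.sequence))
                    truth.append(
                        Plant(iso_id, plant.motif_text, plant.start, plant.end, plant.gap_lengths)
                    )
            break
        else:
            raise GenerationError(
                f"could not generate an exclusive record after {max_retries} tries"
            )
    params = {
        "n_records": n_records,
        "length": length,
        "seed": seed,
        "isoform_duplication": isoform_duplication,
        "exclusive": exclusive,
        "freqs": freqs,
        "plants": [
            {"motif": format_motif(s.motif), "count": s.count} for s in plants
        ],
    }
    return PlantedProteomeTruth(records, truth, params)


def _plant_is_exclusive(
    record: ProteinRecord, plant: Plant | None, watch: Sequence[Motif]
) -> bool:
    """Every watched-motif match must lie inside the planted span (if any)."""
    for m in watch:
        for hit in find_matches(m, record, ALL_REALIZATIONS):
            if plant is None:
                return False
            if hit.start < plant.start or hit.end > plant.end:
                return False
    return True


def write_proteome(truth: PlantedProteomeTruth, fasta_path, truth_path=None) -> None:
    """FASTA (60-column wrapped) plus a ground-truth JSON sidecar."""
    with open(fasta_path, "w") as fh:
        for rec in truth.records:
            fh.write(f">{rec.seq_id} {rec.description}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(
                {
                    "generator_params": truth.generator_params,
                    "plants": [
                        {
                            "seq_id": pl.seq_id,
                            "motif": pl.motif_text,
                            "start": pl.start,
                            "end": pl.end,
                            "gap_lengths": list(pl.gap_lengths),
                        }
                        for pl in truth.plants
                    ],
                },
                fh,
                indent=2,
            )


def expected_random_hits(
    motif: Motif, seq_length: int, freqs: dict[str, float] | None = None
) -> float:
    """Expected realization count on one i.i.d. random sequence.

    Closed form: sum over gap vectors g of (L - span(g) + 1)+ times the
    product of the fixed-residue frequencies (gap positions match any
    residue, probability 1).
    """
    letters, p = _freq_arrays(freqs)
    lookup = dict(zip(letters, p))
    fixed_prob = 1.0
    for i in motif.fixed_indices:
        fixed_prob *= lookup.get(motif.tokens[i].residue, 0.0)
    total = 0.0
    for gv in motif.gap_vectors():
        span = realization_length(motif, gv)
        total += max(seq_length - span + 1, 0) * fixed_prob
    return total


# ---------------------------------------------------------------------------
# spectra

@dataclass(frozen=True)
class Band:
    center: float  # nm
    width: float   # Gaussian sigma, nm
    height: float  # AU


@dataclass(frozen=True)
class SpectrumTemplate:
    """Bands + linear baseline + noise level defining one heme state."""

    state: str
    bands: tuple[Band, ...]
    baseline: tuple[float, float] = (0.02, -0.00002)  # (intercept, slope per nm)
    noise_sd: float = 0.0


# Built-in templates use the canonical band centers: ferric 408 (with the
# weak broad ~530 nm feature), ferrous 418/525/553, 5c-NO 398, free hemin
# 436 with a ~400 nm shoulder, and apo with no bands at all.
STATE_TEMPLATES: dict[str, SpectrumTemplate] = {
    sp.FERRIC_HIS_LIGATED: SpectrumTemplate(
        sp.FERRIC_HIS_LIGATED,
        (Band(408.0, 12.0, 0.50), Band(530.0, 22.0, 0.05)),
    ),
    sp.FERROUS_6C: SpectrumTemplate(
        sp.FERROUS_6C,
        (Band(418.0, 12.0, 0.50), Band(525.0, 7.0, 0.08), Band(553.0, 7.0, 0.08)),
    ),
    sp.FERROUS_5C_NO: SpectrumTemplate(
        sp.FERROUS_5C_NO,
        (Band(398.0, 14.0, 0.45),),
    ),
    sp.FREE_HEMIN: SpectrumTemplate(
        sp.FREE_HEMIN,
        (Band(436.0, 10.0, 0.40), Band(400.0, 22.0, 0.18)),
    ),
    sp.APO_NO_HEME: SpectrumTemplate(sp.APO_NO_HEME, tuple()),
}


def template_for(state: str, noise_sd: float = 0.0) -> SpectrumTemplate:
    if state not in STATE_TEMPLATES:
        raise GenerationError(f"no built-in template for state {state!r}")
    t = STATE_TEMPLATES[state]
    return SpectrumTemplate(t.state, t.bands, t.baseline, noise_sd)


def _clean_curve(template: SpectrumTemplate, wl: np.ndarray) -> np.ndarray:
    y = template.baseline[0] + template.baseline[1] * wl
    for band in template.bands:
        y = y + band.height * np.exp(-0.5 * ((wl - band.center) / band.width) ** 2)
    return y


def default_grid(start: float = 350.0, stop: float = 600.0, step: float = 1.0) -> np.ndarray:
    return np.arange(start, stop + step / 2, step)


def gen_spectrum(
    template: SpectrumTemplate,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> sp.Spectrum:
    """Sum of Gaussian bands + linear baseline + seeded Gaussian noise."""
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    for band in template.bands:
        if not (wl[0] <= band.center <= wl[-1]):
            raise GenerationError(
                f"band center {band.center} nm outside grid "
                f"{wl[0]:.0f}-{wl[-1]:.0f} nm"
            )
    y = _clean_curve(template, wl)
    if template.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, template.noise_sd, size=wl.shape)
    return sp.Spectrum(wl, y, label=template.state)


def gen_titration(
    K_app: float,
    concentrations: Sequence[float],
    end_states: tuple[SpectrumTemplate, SpectrumTemplate] | None = None,
    seed: int = 0,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
) -> sp.TitrationSeries:
    """NO-donor titration: hyperbolic binding isotherm between two end states.

    At donor concentration c the bound fraction is f = c / (K_app + c);
    step spectra mix the clean ferrous (f=0) and 5c-nitrosyl (f=1) curves
    accordingly, then add seeded noise.
    """
    if K_app <= 0:
        raise GenerationError("K_app must be positive")
    if end_states is None:
        end_states = (template_for(sp.FERROUS_6C), template_for(sp.FERROUS_5C_NO))
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    y0 = _clean_curve(end_states[0], wl)
    y1 = _clean_curve(end_states[1], wl)
    rng = np.random.default_rng(seed)
    steps = []
    for c in concentrations:
        f = c / (K_app + c)
        y = (1 - f) * y0 + f * y1
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=wl.shape)
        steps.append(
            sp.TitrationStep(float(c), sp.Spectrum(wl, y, label=f"{c:g} uM"))
        )
    return sp.TitrationSeries(tuple(steps))


def gen_dissociation(
    rate_k: float,
    times: Sequence[float],
    end_states: tuple[SpectrumTemplate, SpectrumTemplate] | None = None,
    seed: int = 0,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
) -> list[tuple[float, sp.Spectrum]]:
    """First-order NO release: ferric fraction 1 - exp(-k t) mixes end states."""
    if rate_k <= 0:
        raise GenerationError("rate_k must be positive")
    if list(times) != sorted(times):
        raise GenerationError("times must be ascending")
    if end_states is None:
        end_states = (template_for(sp.FERROUS_5C_NO), template_for(sp.FERRIC_HIS_LIGATED))
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    y0 = _clean_curve(end_states[0], wl)
    y1 = _clean_curve(end_states[1], wl)
    rng = np.random.default_rng(seed)
    out = []
    for t in times:
        phi = 1.0 - math.exp(-rate_k * t)
        y = (1 - phi) * y0 + phi * y1
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=wl.shape)
        out.append((float(t), sp.Spectrum(wl, y, label=f"t={t:g}")))
    return out
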