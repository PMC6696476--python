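"""End-to-end workflow: motif -> (relax) -> scan -> candidates -> spectra.

A run is driven by a single JSON/YAML-style config dict validated up
front.  The discovery stage builds or parses a motif, optionally relaxes
it at named interior residues, scans one or more FASTA proteomes, and
writes match tables, a per-locus candidate table, and a machine-readable
run report.  The validation stage classifies spectra listed in a
manifest and analyzes titration / dissociation series.  Identical config
and inputs byte-reproduce all outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from .builder import read_alignment, build_motif
from .motif import Motif, format_motif, motif_to_json, parse_motif, relax, relax_letter
from .scan import (
    ALL_REALIZATIONS,
    CandidateTable,
    MatchSet,
    collapse_to_loci,
    read_fasta,
    scan_proteome,
)
from .spectra import (
    ClassifierConfig,
    TitrationSeries,
    TitrationStep,
    analyze_dissociation,
    analyze_titration,
    classify_spectrum,
    read_spectrum_csv,
)

log = logging.getLogger("hnox_scout")


class ConfigError(ValueError):
    """Config that fails up-front validation (exit code 2 at the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed after validation (exit code 1 at the CLI)."""


@dataclass
class RunConfig:
    """Validated run configuration.

    Exactly one motif source (text or alignment+critical columns) must be
    given, and every referenced path must exist at validation time.
    """

    motif_text: str | None = None
    alignment_path: str | None = None
    critical_columns: list[int] = field(default_factory=list)
    relax_residues: list[str] = field(default_factory=list)
    fasta_paths: list[str] = field(default_factory=list)
    policy: str = ALL_REALIZATIONS
    spectra_manifest: str | None = None
    out_dir: str = "hnox_scout_out"
    seed: int = 0
    classifier_overrides: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        motif_block = raw.get("motif", {})
        cfg = cls(
            motif_text=motif_block.get("text"),
            alignment_path=motif_block.get("alignment"),
            critical_columns=list(motif_block.get("critical_columns", [])),
            relax_residues=list(raw.get("relax", [])),
            fasta_paths=list(raw.get("fasta", [])),
            policy=raw.get("policy", ALL_REALIZATIONS),
            spectra_manifest=raw.get("spectra_manifest"),
            out_dir=raw.get("out_dir", "hnox_scout_out"),
            seed=int(raw.get("seed", 0)),
            classifier_overrides=dict(raw.get("classifier", {})),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        has_text = self.motif_text is not None
        has_aln = self.alignment_path is not None
        if has_text == has_aln:
            raise ConfigError(
                "config must give exactly one motif source: motif.text or "
                "motif.alignment (+ critical_columns)"
            )
        if has_aln and not self.critical_columns:
            raise ConfigError("motif.alignment requires motif.critical_columns")
        for path in [
            *( [self.alignment_path] if has_aln else [] ),
            *self.fasta_paths,
            *( [self.spectra_manifest] if self.spectra_manifest else [] ),
        ]:
            if not Path(path).exists():
                raise ConfigError(f"referenced path does not exist: {path}")

    def classifier_config(self) -> ClassifierConfig:
        base = ClassifierConfig()
        known = set(base.__dataclass_fields__)
        bad = set(self.classifier_overrides) - known
        if bad:
            raise ConfigError(f"unknown classifier options: {sorted(bad)}")
        coerced = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in self.classifier_overrides.items()
        }
        return ClassifierConfig(**coerced)


def _resolve_motif(config: RunConfig) -> Motif:
    if config.motif_text is not None:
        return parse_motif(config.motif_text)
    aln = read_alignment(config.alignment_path, config.critical_columns)
    return build_motif(aln)


def run_discovery(config: RunConfig) -> dict:
    """Motif construction, optional relaxation, proteome scan, candidate tables.

    Writes, under ``out_dir``: ``motif_<name>.json``, ``matches_<name>.tsv``,
    ``candidates_<name>.tsv`` for the base motif and each relaxed variant,
    plus ``report.json`` with counts and provenance.  Returns the report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()

    try:
        base = _resolve_motif(config)
    except Exception as exc:
        raise StageError(f"motif stage: {exc}") from exc

    variants: list[tuple[str, Motif]] = [("base", base)]
    current = base
    for letter in config.relax_residues:
        try:
            current = relax_letter(current, letter)
        except Exception as exc:
            raise StageError(f"relax stage ({letter!r}): {exc}") from exc
        variants.append((f"relaxed_{letter}", current))

    try:
        records = []
        for path in config.fasta_paths:
            records.extend(read_fasta(path))
    except Exception as exc:
        raise StageError(f"fasta stage: {exc}") from exc

    report: dict = {
        "tool": "hnox-scout",
        "version": __version__,
        "seed": config.seed,
        "policy": config.policy,
        "n_records": len(records),
        "motifs": {},
    }
    for name, motif in variants:
        (out / f"motif_{name}.json").write_text(motif_to_json(motif))
        try:
            ms = scan_proteome(motif, records, config.policy)
        except Exception as exc:
            raise StageError(f"scan stage ({name}): {exc}") from exc
        table = collapse_to_loci(ms)
        ms.to_frame().to_csv(out / f"matches_{name}.tsv", sep="\t", index=False)
        table.to_frame().to_csv(out / f"candidates_{name}.tsv", sep="\t", index=False)
        report["motifs"][name] = {
            "motif": format_motif(motif),
            "n_matching_records": ms.n_matching_records,
            "n_realizations": ms.n_realizations,
            "n_loci": table.n_loci,
        }
        log.info(
            "scan %-12s %-22s records=%d realizations=%d loci=%d",
            name, format_motif(motif), ms.n_matching_records,
            ms.n_realizations, table.n_loci,
        )
    report["elapsed_s"] = round(time.monotonic() - t0, 3)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def run_validation(config: RunConfig) -> dict:
    """Classify manifest spectra; analyze titration/dissociation series.

    The manifest is JSON: ``{"spectra": [{"file", "label"}...],
    "titration": {"tolerance", "steps": [{"concentration_uM", "file"}...]},
    "dissociation": {"steps": [{"time_h", "file"}...]}}`` with paths
    relative to the manifest.  Writes ``state_calls.tsv`` and
    ``validation.json``; returns the latter as a dict.
    """
    if not config.spectra_manifest:
        raise ConfigError("validation requires a spectra manifest")
    manifest_path = Path(config.spectra_manifest)
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"malformed manifest {manifest_path}: {exc}") from exc
    if not isinstance(manifest, dict) or not any(
        k in manifest for k in ("spectra", "titration", "dissociation")
    ):
        raise ConfigError(
            f"manifest {manifest_path} lists no spectra, titration or dissociation"
        )
    root = manifest_path.parent
    cls_config = config.classifier_config()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result: dict = {"tool": "hnox-scout", "version": __version__}

    missing = [
        str(root / e["file"])
        for section in ("spectra",)
        for e in manifest.get(section, [])
        if not (root / e["file"]).exists()
    ]
    for block in ("titration", "dissociation"):
        for e in manifest.get(block, {}).get("steps", []):
            if not (root / e["file"]).exists():
                missing.append(str(root / e["file"]))
    if missing:
        raise ConfigError(f"manifest entries point to missing files: {missing}")

    if manifest.get("spectra"):
        rows = []
        for entry in manifest["spectra"]:
            spec = read_spectrum_csv(root / entry["file"], entry.get("label"))
            call = classify_spectrum(spec, cls_config)
            rows.append(
                {
                    "label": spec.label,
                    "state": call.state,
                    "peaks": ";".join(
                        f"{p.band_class}@{p.lambda_max:.1f}" for p in call.supporting_peaks
                    ),
                    "rationale": call.rationale,
                }
            )
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "state_calls.tsv", sep="\t", index=False)
        result["state_calls"] = rows

    if manifest.get("titration"):
        block = manifest["titration"]
        steps = tuple(
            TitrationStep(
                float(e["concentration_uM"]), read_spectrum_csv(root / e["file"])
            )
            for e in block["steps"]
        )
        sat = analyze_titration(TitrationSeries(steps), float(block.get("tolerance", 0.005)))
        result["titration"] = {
            "saturated": sat.saturated,
            "saturation_index": sat.saturation_index,
            "saturation_concentration_uM": sat.saturation_concentration,
            "max_residual_change_AU": sat.max_residual_change,
        }

    if manifest.get("dissociation"):
        block = manifest["dissociation"]
        series = [
            (float(e["time_h"]), read_spectrum_csv(root / e["file"]))
            for e in block["steps"]
        ]
        diss = analyze_dissociation(series, cls_config)
        result["dissociation"] = {
            "recovered": diss.recovered,
            "recovery_time_h": diss.recovery_time,
            "states": list(diss.states),
        }

    (out / "validation.json").write_text(json.dumps(result, indent=2))
    return result
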