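"""End-to-end pipeline: simulate → preprocess → coherence → compare → report.

A run is fully described by a :class:`PipelineConfig` (constructible from
YAML); given a seed it is deterministic, and every output carries the config
hash and seed as provenance.

The report always populates all (band × condition) cells — 22 with the
default 11 bands — with the count of FDR-significant edges, the count in the
case-deficit direction, and a per-region summary, whether or not anything is
significant.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .connectivity import difference_graph, group_median, region_summary, threshold_graph
from .exceptions import ConfigurationError, DataError
from .group_stats import edgewise_comparison
from .io import (
    load_recording,
    read_edf,
    write_edge_results_tsv,
    write_profiles_tsv,
)
from .montage import Montage
from .preprocessing import EpochSet, PreprocessConfig, preprocess_recording
from .spectral import (
    DEFAULT_BANDS,
    BandDefinition,
    WelchConfig,
    subject_coherence_profile,
)
from .synthetic import SourceSpec, SynthConfig, demo_config, generate_cohort, null_config

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run needs.

    Either ``simulate`` holds a :class:`SynthConfig` (synthetic cohort) or
    ``input_dir`` points at EDF / fixture recordings on disk.
    """

    simulate: SynthConfig | None = None
    input_dir: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    welch: WelchConfig = field(default_factory=WelchConfig)
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    thresholds: tuple[float, ...] = (0.5, 0.7)
    q_cutoff: float = 0.05
    out_dir: str = "neurocoh_out"
    seed: int = 0

    @staticmethod
    def demo(n_per_group: int = 12, seed: int = 0, out_dir: str = "neurocoh_out") -> "PipelineConfig":
        return PipelineConfig(simulate=demo_config(n_per_group=n_per_group, seed=seed),
                              out_dir=out_dir, seed=seed)

    @staticmethod
    def null(n_per_group: int = 12, seed: int = 0, out_dir: str = "neurocoh_out") -> "PipelineConfig":
        return PipelineConfig(simulate=null_config(n_per_group=n_per_group, seed=seed),
                              out_dir=out_dir, seed=seed)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_config_to_dict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _config_to_dict(cfg: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            if isinstance(obj, Montage):
                return {"labels": list(obj.labels)}
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    return {
        "simulate": enc(cfg.simulate) if cfg.simulate else None,
        "input_dir": cfg.input_dir,
        "preprocess": enc(cfg.preprocess),
        "welch": enc(cfg.welch),
        "bands": [[b.name, b.low, b.high] for b in cfg.bands],
        "thresholds": list(cfg.thresholds),
        "q_cutoff": cfg.q_cutoff,
        "seed": cfg.seed,
    }


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file.

    The ``simulate`` block is either ``off``, a preset
    (``preset: demo|null`` with optional ``n_per_group``, ``seed``,
    ``case_deficit_scale``), or a full source-by-source specification.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ConfigurationError(f"cannot parse config: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a YAML mapping")

    seed = int(raw.get("seed", 0))
    sim_raw = raw.get("simulate", "off")
    simulate = None
    if isinstance(sim_raw, dict):
        preset = sim_raw.get("preset")
        if preset in ("demo", "null"):
            make = demo_config if preset == "demo" else null_config
            kwargs = {k: sim_raw[k] for k in ("n_per_group", "case_deficit_scale")
                      if k in sim_raw and (preset == "demo" or k != "case_deficit_scale")}
            simulate = make(seed=int(sim_raw.get("seed", seed)), **kwargs)
        else:
            sources = tuple(
                SourceSpec(
                    center_freq=float(s["center_freq"]),
                    bandwidth=float(s["bandwidth"]),
                    target_channels=tuple(s["target_channels"]),
                    gain=float(s.get("gain", 1.0)),
                    group_gain_scale=dict(s.get("group_gain_scale", {})),
                    condition_gain_scale=dict(s.get("condition_gain_scale", {})),
                    jitter_sigma=float(s.get("jitter_sigma", 0.10)),
                )
                for s in sim_raw.get("sources", [])
            )
            simulate = SynthConfig(
                n_per_group=int(sim_raw.get("n_per_group", 12)),
                sources=sources,
                noise_exponent=float(sim_raw.get("noise_exponent", 1.0)),
                noise_sd=float(sim_raw.get("noise_sd", 1.0)),
                fs=float(sim_raw.get("fs", 250.0)),
                epoch_s=float(sim_raw.get("epoch_s", 60.0)),
                n_epochs=int(sim_raw.get("n_epochs", 3)),
                seed=int(sim_raw.get("seed", seed)),
            )

    pp = raw.get("preprocess", {}) or {}
    wl = raw.get("welch", {}) or {}
    bands_raw = raw.get("bands")
    bands = (
        tuple(BandDefinition(b["name"], float(b["low"]), float(b["high"])) for b in bands_raw)
        if bands_raw
        else DEFAULT_BANDS
    )
    return PipelineConfig(
        simulate=simulate,
        input_dir=raw.get("input_dir"),
        preprocess=PreprocessConfig(
            highpass=float(pp.get("highpass", 0.5)),
            lowpass=float(pp.get("lowpass", 35.0)),
            kurtosis_z_threshold=float(pp.get("kurtosis_z_threshold", 5.0)),
            discard_lead_s=float(pp.get("discard_lead_s", 4.0)),
            epoch_s=float(pp.get("epoch_s", 56.0)),
        ),
        welch=WelchConfig(
            segment_s=float(wl.get("segment_s", 2.0)),
            overlap_fraction=float(wl.get("overlap_fraction", 0.5)),
            window=str(wl.get("window", "hann")),
            detrend=str(wl.get("detrend", "constant")),
        ),
        bands=bands,
        thresholds=tuple(raw.get("thresholds", (0.5, 0.7))),
        q_cutoff=float(raw.get("q_cutoff", 0.05)),
        out_dir=str(raw.get("out_dir", "neurocoh_out")),
        seed=seed,
    )


def validate_config(cfg: PipelineConfig) -> list[str]:
    """All detectable config problems, without side effects."""
    issues: list[str] = []
    if not cfg.bands:
        issues.append("bands list is empty")
    df = cfg.welch.delta_f()
    fs = cfg.simulate.fs if cfg.simulate else 250.0
    freqs = np.arange(0.0, fs / 2.0 + df / 2, df)
    for b in cfg.bands:
        if not np.any(b.mask(freqs)):
            issues.append(
                f"band {b.name} [{b.low}, {b.high}) holds no Welch bin at Δf={df:g} Hz"
            )
    for t in cfg.thresholds:
        if not 0 <= t <= 1:
            issues.append(f"threshold {t} outside [0, 1]")
    if not 0 < cfg.q_cutoff < 1:
        issues.append(f"q_cutoff {cfg.q_cutoff} outside (0, 1)")
    # partial overlaps among bands (containment, e.g. sub-band in parent, is fine)
    for a in cfg.bands:
        for b in cfg.bands:
            if a.name >= b.name:
                continue
            lo, hi = max(a.low, b.low), min(a.high, b.high)
            if lo < hi:
                contained = (a.low <= b.low and b.high <= a.high) or (
                    b.low <= a.low and a.high <= b.high
                )
                if not contained:
                    issues.append(f"bands {a.name} and {b.name} partially overlap")
    if cfg.simulate is None and cfg.input_dir is None:
        issues.append("neither simulate nor input_dir is set")
    return issues


@dataclass
class RunReport:
    """Per-cell significance counts plus provenance."""

    cells: dict[str, dict]  # key "band/condition"
    provenance: dict

    def to_json(self) -> str:
        return json.dumps({"cells": self.cells, "provenance": self.provenance},
                          indent=1, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"neurocoh run (version {self.provenance['version']}, "
            f"seed {self.provenance['seed']}, config {self.provenance['config_hash']})",
            f"subjects: {self.provenance['n_subjects']}, "
            f"channels: {self.provenance['n_channels']}, q_cutoff: {self.provenance['q_cutoff']}",
            "",
            f"{'band':<8} {'cond':<5} {'sig':>5} {'deficit':>8}",
        ]
        for key, cell in self.cells.items():
            band, cond = key.split("/")
            lines.append(
                f"{band:<8} {cond:<5} {cell['n_significant']:>5} {cell['n_deficit']:>8}"
            )
        return "\n".join(lines)

    def cell(self, band: str, condition: str) -> dict:
        return self.cells[f"{band}/{condition}"]


def _load_recordings(input_dir: str) -> list:
    d = Path(input_dir)
    recs = []
    for p in sorted(d.glob("*.json")):
        recs.append(load_recording(p.with_suffix("")))
    for p in sorted(d.glob("*.edf")):
        recs.append(read_edf(p))
    if not recs:
        raise DataError(f"no recordings found in {input_dir}")
    return recs


def _harmonize_channels(epochsets: list[EpochSet]) -> list[EpochSet]:
    """Restrict all epoch sets to the channels retained in every subject."""
    common = set(epochsets[0].montage.labels)
    for es in epochsets[1:]:
        common &= set(es.montage.labels)
    if not common:
        raise DataError("no channel retained across all subjects")
    out = []
    for es in epochsets:
        if set(es.montage.labels) == common:
            out.append(es)
            continue
        keep = [lab for lab in es.montage.labels if lab in common]
        rows = [es.montage.index(lab) for lab in keep]
        out.append(
            EpochSet(
                subject_id=es.subject_id, group=es.group, condition=es.condition,
                epochs=[e[rows] for e in es.epochs], fs=es.fs,
                montage=es.montage.subset(keep),
                rejected_channels=es.rejected_channels,
            )
        )
    return out


def run_pipeline(cfg: PipelineConfig, save_outputs: bool = True) -> RunReport:
    """Run simulate → preprocess → coherence → compare → report.

    Writes the coherence profile table, per-cell edge statistics, graph edge
    lists and the report (JSON + text) into ``cfg.out_dir`` unless
    ``save_outputs`` is False.  Deterministic given the config.
    """
    issues = validate_config(cfg)
    fatal = [i for i in issues if "partially overlap" not in i]
    if fatal:
        raise ConfigurationError("invalid config: " + "; ".join(fatal))

    if cfg.simulate is not None:
        recordings = generate_cohort(cfg.simulate)
    else:
        recordings = _load_recordings(cfg.input_dir)
    logger.info("pipeline: %d recordings", len(recordings))

    epochsets: list[EpochSet] = []
    for rec in recordings:
        eo, ec = preprocess_recording(rec, cfg.preprocess)
        epochsets += [eo, ec]
    epochsets = _harmonize_channels(epochsets)
    channels = epochsets[0].montage.labels
    montage = epochsets[0].montage

    profiles = [subject_coherence_profile(es, cfg.welch, cfg.bands) for es in epochsets]

    out = Path(cfg.out_dir)
    if save_outputs:
        out.mkdir(parents=True, exist_ok=True)
        write_profiles_tsv(profiles, out / "coherence_profiles.tsv")

    conditions = sorted({p.condition for p in profiles})
    cells: dict[str, dict] = {}
    for band in cfg.bands:
        for cond in conditions:
            results = edgewise_comparison(profiles, band.name, cond)
            dg = difference_graph(results, cfg.q_cutoff)
            med_case = group_median(profiles, "case", cond, band.name)
            med_control = group_median(profiles, "control", cond, band.name)
            graphs = {
                (grp, t): threshold_graph(
                    med, t, channels, group=grp, condition=cond, band=band.name
                )
                for grp, med in (("case", med_case), ("control", med_control))
                for t in cfg.thresholds
            }
            regions = region_summary(dg, montage)
            cells[f"{band.name}/{cond}"] = {
                "n_significant": sum(1 for r in results if r.q <= cfg.q_cutoff),
                "n_deficit": len(dg.edges),
                "n_excess": len(dg.reversed_edges),
                "deficit_edges": sorted([list(e) for e in dg.edges]),
                "region_summary": {
                    f"{a}|{b}": v for (a, b), v in regions.items() if v["count"] > 0
                },
                "threshold_edge_counts": {
                    f"{grp}@{t:g}": len(g.edges) for (grp, t), g in graphs.items()
                },
            }
            if save_outputs:
                write_edge_results_tsv(results, out / f"edges_{band.name}_{cond}.tsv")

    report = RunReport(
        cells=cells,
        provenance={
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "n_subjects": len(recordings),
            "n_channels": len(channels),
            "q_cutoff": cfg.q_cutoff,
            "welch": {"segment_s": cfg.welch.segment_s,
                      "overlap_fraction": cfg.welch.overlap_fraction},
        },
    )
    if save_outputs:
        (out / "report.json").write_text(report.to_json())
        (out / "report.txt").write_text(report.to_text())
    return report
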