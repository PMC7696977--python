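"""Workflow orchestration: configuration, manifests and the three stages.

``RunConfig`` carries input paths and per-stage parameters; defaults are
the study's stated values (1 kb TSS exclusion, <50 bp peak merge, 50%
overlap, +-5 kb windows in 100 bp bins, summit +-25 bp motif windows,
alpha 0.05, |log2FC| >= 1, 10 kb enhancer neighborhood, >= 5 peaks to
report).  Precedence is CLI override > config file > defaults; unknown keys
are rejected.  Every run writes a machine-readable manifest with input and
output checksums so identical configurations are verifiably reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any, Callable

from terk import intervals, motifs, peaks as peaks_mod, profiles, quant
from terk import expression as expr

logger = logging.getLogger(__name__)

PARAM_DEFAULTS: dict[str, Any] = {
    "family": "LTR5_Hs",
    "filter.tss_exclusion_bp": 1000,
    "merge.max_gap_bp": 50,
    "assign.min_frac": 0.5,
    "assign.overlap_on": "peak",
    "enrich.model": "span",
    "enrich.min_peaks": 5,
    "profile.flank_bp": 5000,
    "profile.bin_bp": 100,
    "profile.anchor": "five-prime",
    "profile.aggregate": "mean",
    "motif.flank_bp": 25,
    "quant.tol": 1e-8,
    "quant.max_iter": 1000,
    "quant.read_overlap_frac": 0.5,
    "quant.total_mappable_reads": None,
    "deg.alpha": 0.05,
    "deg.min_abs_lfc": 1.0,
    "enhancer.neighborhood_bp": 10000,
    "enhancer.reciprocal_sign": "down",
    "overlap.method": "chi2",
}

INPUT_KEYS = {
    "repeats", "genes", "sam", "bedgraph", "peaks", "fasta",
    "de_treatment", "de_states", "bound_loci", "set_a", "set_b", "universe",
}

_INT_PARAMS = {
    "filter.tss_exclusion_bp", "merge.max_gap_bp", "enrich.min_peaks",
    "profile.flank_bp", "profile.bin_bp", "motif.flank_bp", "quant.max_iter",
    "quant.total_mappable_reads", "enhancer.neighborhood_bp",
}
_FLOAT_PARAMS = {
    "assign.min_frac", "quant.tol", "quant.read_overlap_frac",
    "deg.alpha", "deg.min_abs_lfc",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=lambda: dict(PARAM_DEFAULTS))
    seed: int = 0
    outdir: str = "terk_out"

    @classmethod
    def load(cls, path: str, overrides: dict[str, Any] | None = None) -> "RunConfig":
        """Plain key=value config; ``input.<name>`` keys name input files."""
        cfg = cls()
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}: line {ln}: expected key=value")
                key, value = (s.strip() for s in line.split("=", 1))
                cfg.set(key, value)
        for key, value in (overrides or {}).items():
            if value is not None:
                cfg.set(key, value)
        return cfg

    def set(self, key: str, value: Any) -> None:
        if key == "seed":
            self.seed = int(value)
        elif key == "outdir":
            self.outdir = str(value)
        elif key.startswith("input."):
            name = key[len("input."):]
            if name not in INPUT_KEYS:
                raise ConfigError(f"unknown input {name!r}")
            self.inputs[name] = str(value)
        elif key in PARAM_DEFAULTS:
            if key in _INT_PARAMS:
                value = int(value)
            elif key in _FLOAT_PARAMS:
                value = float(value)
            self.params[key] = value
        else:
            raise ConfigError(f"unknown config key {key!r}")

    def require_inputs(self, *names: str) -> None:
        missing = [n for n in names if n not in self.inputs]
        if missing:
            raise ConfigError(f"missing required inputs: {', '.join(missing)}")
        absent = [self.inputs[n] for n in names if not os.path.exists(self.inputs[n])]
        if absent:
            raise ConfigError(f"input files not found: {', '.join(absent)}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, cfg: RunConfig, workflow: str):
        self.data: dict[str, Any] = {
            "workflow": workflow,
            "seed": cfg.seed,
            "params": dict(cfg.params),
            "inputs": {n: {"path": p, "sha256": _sha256(p)} for n, p in cfg.inputs.items()
                       if os.path.exists(p)},
            "outputs": {},
            "timings_s": {},
        }
        self._t0 = time.monotonic()
        self._stage_t = self._t0

    def stage(self, name: str) -> None:
        now = time.monotonic()
        self.data["timings_s"][name] = round(now - self._stage_t, 4)
        self._stage_t = now

    def add_output(self, name: str, path: str) -> None:
        self.data["outputs"][name] = {"path": path, "sha256": _sha256(path)}

    def write(self, path: str) -> None:
        self.data["timings_s"]["total"] = round(time.monotonic() - self._t0, 4)
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)


def _filtered_loci(cfg: RunConfig):
    loci = intervals.load_repeat_annotation(cfg.inputs["repeats"])
    genes = intervals.load_gene_models(cfg.inputs["genes"])
    return intervals.filter_te_loci(loci, genes, cfg.params["filter.tss_exclusion_bp"]), genes


def run_expression_workflow(cfg: RunConfig) -> Manifest:
    """filter-loci -> quant-family -> quant-locus."""
    cfg.require_inputs("repeats", "genes", "sam")
    total = cfg.params["quant.total_mappable_reads"]
    if total is None:
        raise ConfigError("quant.total_mappable_reads must be set (never inferred)")
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest = Manifest(cfg, "expression")

    loci, _ = _filtered_loci(cfg)
    bed = os.path.join(cfg.outdir, "filtered_loci.bed")
    intervals.write_bed(loci, bed)
    manifest.stage("filter_loci")

    alignments = quant.read_sam(cfg.inputs["sam"])
    frac = cfg.params["quant.read_overlap_frac"]
    fc = quant.family_counts(alignments, loci, int(total), frac)
    fc_path = os.path.join(cfg.outdir, "family_counts.tsv")
    quant.write_family_counts(fc, fc_path)
    manifest.stage("quant_family")

    fam_loci = [l for l in loci if l.family == cfg.params["family"]]
    lc = quant.em_locus_quant(
        alignments, fam_loci, cfg.params["quant.tol"], cfg.params["quant.max_iter"], frac
    )
    lc_path = os.path.join(cfg.outdir, "locus_counts.tsv")
    quant.write_locus_counts(lc, lc_path)
    manifest.stage("quant_locus")

    for name, path in [("filtered_loci", bed), ("family_counts", fc_path), ("locus_counts", lc_path)]:
        manifest.add_output(name, path)
    manifest.write(os.path.join(cfg.outdir, "manifest_expression.json"))
    return manifest


def run_regulatory_workflow(cfg: RunConfig) -> Manifest:
    """profile -> peak-enrich -> motif-test over one filtered locus set."""
    cfg.require_inputs("repeats", "genes", "bedgraph", "peaks")
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest = Manifest(cfg, "regulatory")

    loci, _ = _filtered_loci(cfg)
    fam = cfg.params["family"]
    fam_loci = [l for l in loci if l.family == fam]
    manifest.stage("filter_loci")

    track = profiles.SignalTrack.read_bedgraph(cfg.inputs["bedgraph"])
    pm = profiles.build_profile(
        track, fam_loci, cfg.params["profile.flank_bp"], cfg.params["profile.bin_bp"],
        cfg.params["profile.anchor"], cfg.params["profile.aggregate"],
    )
    profile_path = os.path.join(cfg.outdir, "profile.tsv")
    pm.write_tsv(profile_path)
    manifest.stage("profile")

    raw_peaks = peaks_mod.read_peaks(cfg.inputs["peaks"])
    enrich_path = os.path.join(cfg.outdir, "enrichment.tsv")
    bound_path = os.path.join(cfg.outdir, "bound_loci.txt")
    if raw_peaks:
        merged = intervals.merge_intervals(
            [p.interval for p in raw_peaks], cfg.params["merge.max_gap_bp"]
        )
        merged_peaks = [peaks_mod.PeakRecord(iv) for iv in merged]
        assignment = peaks_mod.assign_peaks_to_te(
            merged_peaks, loci, cfg.params["assign.min_frac"], cfg.params["assign.overlap_on"]
        )
        expected = peaks_mod.expected_family_peaks(
            assignment.n_assigned, loci, cfg.params["enrich.model"]
        )
        results = peaks_mod.family_enrichment_test(assignment.family_counts, expected)
        peaks_mod.reporting_filter(results, cfg.params["enrich.min_peaks"])
        bound_ids = sorted(assignment.bound_loci.get(fam, set()))
    else:
        logger.warning("empty peak file: writing empty enrichment table")
        results, bound_ids = [], []
    peaks_mod.write_enrichment(results, enrich_path)
    with open(bound_path, "w") as fh:
        fh.writelines(f"{lid}\n" for lid in bound_ids)
    manifest.stage("peak_enrich")

    outputs = [("profile", profile_path), ("enrichment", enrich_path), ("bound_loci", bound_path)]
    if "fasta" in cfg.inputs and bound_ids:
        bound_set = set(bound_ids)
        bound_loci = [l for l in fam_loci if l.locus_id in bound_set]
        unbound_loci = [l for l in fam_loci if l.locus_id not in bound_set]
        if bound_loci and unbound_loci:
            bseq = motifs.fetch_sequences(
                cfg.inputs["fasta"], [l.interval for l in bound_loci],
                [l.locus_id for l in bound_loci],
            )
            useq = motifs.fetch_sequences(
                cfg.inputs["fasta"], [l.interval for l in unbound_loci],
                [l.locus_id for l in unbound_loci],
            )
            table = motifs.motif_presence_test(bseq, useq)
            mt_path = os.path.join(cfg.outdir, "motif_test.tsv")
            with open(mt_path, "w") as fh:
                fh.write("group\twith_motif\twithout_motif\n")
                fh.write(f"bound\t{table.table[0,0]}\t{table.table[0,1]}\n")
                fh.write(f"unbound\t{table.table[1,0]}\t{table.table[1,1]}\n")
                fh.write(f"# chi2={table.chi2:.6g}\tp={table.p:.6g}\n")
            outputs.append(("motif_test", mt_path))
        manifest.stage("motif_test")

    for name, path in outputs:
        manifest.add_output(name, path)
    manifest.write(os.path.join(cfg.outdir, "manifest_regulatory.json"))
    return manifest


def run_integration_workflow(cfg: RunConfig) -> Manifest:
    """DEG lists -> overlap tests -> enhancer candidates."""
    cfg.require_inputs("repeats", "genes", "de_treatment", "de_states", "bound_loci")
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest = Manifest(cfg, "integration")

    loci, genes = _filtered_loci(cfg)
    de_treatment = expr.read_de_table(cfg.inputs["de_treatment"])
    de_states = expr.read_de_table(cfg.inputs["de_states"])
    alpha, min_lfc = cfg.params["deg.alpha"], cfg.params["deg.min_abs_lfc"]

    outputs = []
    for label, table in [("treatment", de_treatment), ("states", de_states)]:
        up, down = expr.deg_filter(table, alpha, min_lfc)
        for direction, recs in [("up", up), ("down", down)]:
            path = os.path.join(cfg.outdir, f"deg_{label}_{direction}.txt")
            with open(path, "w") as fh:
                fh.writelines(f"{r.gene_id}\n" for r in sorted(recs, key=lambda r: r.gene_id))
            outputs.append((f"deg_{label}_{direction}", path))
    manifest.stage("deg")

    if "set_a" in cfg.inputs or "set_b" in cfg.inputs:
        if "universe" not in cfg.inputs:
            raise ConfigError("overlap test requires an explicit universe input")
        cfg.require_inputs("set_a", "set_b", "universe")
        read_list = lambda p: [l.strip() for l in open(p) if l.strip()]
        result = expr.set_overlap_test(
            read_list(cfg.inputs["set_a"]), read_list(cfg.inputs["set_b"]),
            read_list(cfg.inputs["universe"]), cfg.params["overlap.method"],
        )
        path = os.path.join(cfg.outdir, "overlap_test.tsv")
        with open(path, "w") as fh:
            fh.write("method\tin_both\ta_only\tb_only\tneither\tstatistic\tp\n")
            t = result.table
            fh.write(
                f"{result.method}\t{t[0,0]}\t{t[0,1]}\t{t[1,0]}\t{t[1,1]}\t"
                f"{result.statistic:.6g}\t{result.p:.6g}\n"
            )
        outputs.append(("overlap_test", path))
    manifest.stage("overlap")

    with open(cfg.inputs["bound_loci"]) as fh:
        bound_ids = {line.strip() for line in fh if line.strip()}
    candidates = expr.enhancer_candidates(
        genes, loci, bound_ids, de_treatment, de_states,
        cfg.params["enhancer.neighborhood_bp"], cfg.params["family"],
        cfg.params["enhancer.reciprocal_sign"], alpha, min_lfc,
    )
    cand_path = os.path.join(cfg.outdir, "enhancer_candidates.tsv")
    expr.write_candidates(candidates, cand_path)
    outputs.append(("enhancer_candidates", cand_path))
    manifest.stage("enhancers")

    for name, path in outputs:
        manifest.add_output(name, path)
    manifest.write(os.path.join(cfg.outdir, "manifest_integration.json"))
    return manifest


WORKFLOWS: dict[str, Callable[[RunConfig], Manifest]] = {
    "expression": run_expression_workflow,
    "regulatory": run_regulatory_workflow,
    "integration": run_integration_workflow,
}


def workflows_available(cfg: RunConfig) -> list[str]:
    """Workflows whose required inputs are configured."""
    req = {
        "expression": {"repeats", "genes", "sam"},
        "regulatory": {"repeats", "genes", "bedgraph", "peaks"},
        "integration": {"repeats", "genes", "de_treatment", "de_states", "bound_loci"},
    }
    return [w for w, needed in req.items() if needed <= set(cfg.inputs)]
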