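"""End-to-end pipeline orchestration and report emission.

``run_pipeline`` wires the stages together — preprocess, classify, align and
call variants, resolve integration junctions, score microhomology — and
writes a reproducible output bundle: per-read calls, variant table,
integration events, vector coverage, deletion profile, microhomology table
and a summary JSON with the run parameters embedded for provenance. Read
counts are logged at every stage boundary so the partition-conservation
invariants can be audited from the log alone. Given fixed inputs and
configuration the bundle is byte-identical between runs.

Group-level descriptive statistics (mean ± SD across samples) are provided
by ``compare_groups``; inferential statistics are deliberately out of scope.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import integration as _integration
from . import microhomology as _mh
from . import variants as _variants
from .errors import ConfigError
from .refio import arm_boundaries, load_references

logger = logging.getLogger("nickedit")

CLASS_ORDER = ("amplicon_only", "chimeric", "vector_only", "unaligned", "filtered")


@dataclass
class RunConfig:
    """Full parameterisation of one pipeline run."""

    reads: str
    amplicon_path: str
    vector_path: str
    guides_path: str
    out_dir: str
    reads2: str | None = None
    vector_features_path: str | None = None
    seed: int = 0
    # preprocessing
    qual_threshold: int = 20
    trim_window: int = 4
    min_length: int = 50
    merge_pairs: bool | None = None
    # references
    nick_offset: int = 3
    quant_pad: int = 5
    # classification
    classify: _classify.ClassifyParams = field(default_factory=_classify.ClassifyParams)
    # alignment
    scoring: _variants.Scoring = field(default_factory=_variants.Scoring)
    # integration / microhomology
    boundary_tol: int = 3
    mh_threshold: int = 2

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        nested = {}
        for key, sub_cls in (("classify", _classify.ClassifyParams),
                             ("scoring", _variants.Scoring)):
            if key in d and isinstance(d[key], dict):
                sub = d.pop(key)
                unknown = set(sub) - {f.name for f in dataclasses.fields(sub_cls)}
                if unknown:
                    raise ConfigError(f"unknown {key} keys: {sorted(unknown)}")
                nested[key] = sub_cls(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d, **nested)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        return cls.from_dict(data)

    def to_dict(self, include_out_dir: bool = True) -> dict:
        d = dataclasses.asdict(self)
        if not include_out_dir:
            d.pop("out_dir")
        return d

    def validate(self) -> None:
        for label, path in (("reads", self.reads),
                            ("amplicon_path", self.amplicon_path),
                            ("vector_path", self.vector_path),
                            ("guides_path", self.guides_path)):
            if path is None or not Path(path).exists():
                raise ConfigError(f"{label}: file not found: {path}")
        if self.reads2 is not None and not Path(self.reads2).exists():
            raise ConfigError(f"reads2: file not found: {self.reads2}")
        if (self.vector_features_path is not None
                and not Path(self.vector_features_path).exists()):
            raise ConfigError(
                f"vector_features_path: file not found: {self.vector_features_path}")


@dataclass
class PipelineResult:
    summary: _variants.SummaryReport
    variant_table: pd.DataFrame
    events: list
    out_dir: Path


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run every stage and write the output bundle to ``cfg.out_dir``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    amplicon, vector, pair = load_references(
        cfg.amplicon_path, cfg.vector_path, cfg.guides_path,
        vector_features_path=cfg.vector_features_path,
        default_nick_offset=cfg.nick_offset, quant_pad=cfg.quant_pad,
    )
    logger.info("references: amplicon %s (%d bp), vector %s (%d bp), "
                "orientation %s, inter-nick %d bp",
                amplicon.name, len(amplicon), vector.name, len(vector),
                pair.orientation, pair.inter_nick_distance)

    reads, filter_log = _classify.preprocess_reads(
        cfg.reads, cfg.reads2, qual_threshold=cfg.qual_threshold,
        trim_window=cfg.trim_window, min_length=cfg.min_length,
        merge_pairs=cfg.merge_pairs,
    )
    n_filtered = filter_log["input"] - filter_log["passed"]
    logger.info("preprocess: %d in, %d passed, %d dropped",
                filter_log["input"], filter_log["passed"], n_filtered)
    if filter_log["input"] == 0:
        logger.warning("no input reads: emitting a zero-count report")

    vec_index = _classify.build_vector_index(vector, cfg.classify.seed_k)
    local = _classify.make_local_aligner(
        cfg.scoring.match, cfg.scoring.mismatch,
        cfg.scoring.gap_open, cfg.scoring.gap_extend)
    calls = [
        _classify.classify_read(rid, seq, amplicon, vector, cfg.classify,
                                vec_index, local)
        for rid, seq in reads
    ]
    class_counts = {c: 0 for c in CLASS_ORDER}
    class_counts["filtered"] = n_filtered
    for call in calls:
        class_counts[call.cls] += 1
    logger.info("classify: %s", class_counts)

    boundaries = arm_boundaries(vector)
    glocal = _variants.make_glocal_aligner(cfg.scoring)
    events = []
    junction_warnings = 0
    amplicon_calls = [c for c in calls if c.cls == "amplicon_only"]
    for call in [c for c in calls if c.cls == "chimeric"]:
        ev = _integration.resolve_junctions(
            call, amplicon, vector, tol=cfg.boundary_tol,
            scoring=cfg.scoring, aligner=glocal, boundaries=boundaries)
        if ev is None:
            junction_warnings += 1
            call.cls = "amplicon_only"
            class_counts["chimeric"] -= 1
            class_counts["amplicon_only"] += 1
            amplicon_calls.append(call)
        else:
            events.append(ev)
    if junction_warnings:
        logger.warning("%d chimeric reads had no consistent amplicon/vector "
                       "split and were reclassified amplicon_only",
                       junction_warnings)

    alignments = []
    variant_calls = []
    window = amplicon.quant_window
    for call in amplicon_calls:
        aln = _variants.align_to_amplicon(call.seq, amplicon, cfg.scoring,
                                          aligner=glocal)
        aln = _variants.normalize_ops(aln, amplicon)
        alignments.append(aln)
        variant_calls.append((call.read_id, _variants.call_variant(aln, window)))
    logger.info("variants: %d amplicon reads aligned, %d integration events",
                len(variant_calls), len(events))

    table, report = _variants.aggregate(variant_calls, events, class_counts)
    report.junction_warnings = junction_warnings

    profile = _variants.deletion_coverage_profile(alignments, amplicon)
    deletions = table[table["type"] == "deletion"].assign(
        size=lambda df: -df["size"])
    mh_table, mh_sum = _mh.mh_summary(
        deletions[["start", "size", "support"]], amplicon,
        mh_threshold=cfg.mh_threshold)
    report.mh_fraction_gt_threshold = mh_sum["fraction_mh_gt_threshold"]
    report.mh_threshold = cfg.mh_threshold

    cov = _integration.vector_coverage(events, vector, tol=cfg.boundary_tol,
                                       boundaries=boundaries)

    # ---------------- outputs ----------------
    _write_tsv(pd.DataFrame(
        [{
            "read_id": c.read_id, "class": c.cls,
            "anchor_start": c.anchor["t_start"] if c.anchor else "",
            "anchor_end": c.anchor["t_end"] if c.anchor else "",
            "anchor_identity": round(c.anchor["identity"], 4) if c.anchor else "",
            "vector_start": c.vector_hit.vstart if c.vector_hit else "",
            "vector_end": c.vector_hit.vend if c.vector_hit else "",
            "vector_strand": c.vector_hit.strand if c.vector_hit else "",
            "vector_identity": round(c.vector_hit.identity, 4) if c.vector_hit else "",
        } for c in calls]
        , columns=["read_id", "class", "anchor_start", "anchor_end",
                   "anchor_identity", "vector_start", "vector_end",
                   "vector_strand", "vector_identity"]), out / "read_calls.tsv")
    _write_tsv(table, out / "variants.tsv")
    _write_tsv(_integration.events_to_frame(events), out / "events.tsv")
    _write_tsv(cov.to_frame(), out / "vector_coverage.tsv")
    _write_tsv(pd.DataFrame({
        "position": np.arange(len(profile)),
        "deletion_fraction": profile,
    }), out / "deletion_profile.tsv")
    _write_tsv(mh_table, out / "mh_table.tsv")
    (out / "filter_log.json").write_text(json.dumps(filter_log, indent=2, sort_keys=True))
    (out / "arm_summary.json").write_text(json.dumps({
        "per_arm_coverage": cov.per_arm,
        "boundary_fraction": cov.boundary_fraction,
        "breakpoint_hist": {str(k): v for k, v in cov.breakpoint_hist.items()},
        "itr_fraction": _integration.itr_fraction(events, vector),
    }, indent=2, sort_keys=True))
    (out / "mh_summary.json").write_text(json.dumps(mh_sum, indent=2, sort_keys=True))

    summary = {
        **report.to_dict(),
        "quant_window": list(window),
        "cut_sites": list(amplicon.cut_sites),
        "itr_fraction": _integration.itr_fraction(events, vector),
        "boundary_fraction": cov.boundary_fraction,
        "config": cfg.to_dict(include_out_dir=False),
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str))
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    return PipelineResult(report, table, events, out)


def compare_groups(reports: list, labels: list[str]) -> pd.DataFrame:
    """Per-group mean ± SD of the headline frequencies.

    ``reports`` holds :class:`~nickedit.variants.SummaryReport` objects (or
    their dicts) and ``labels`` the group of each. SD uses the sample
    formula and is missing (NaN) for single-sample groups. No hypothesis
    testing is performed.
    """
    if len(reports) != len(labels):
        raise ConfigError("reports and labels must have equal length")
    metrics = ("indel_frequency", "integration_frequency_reads",
               "integration_frequency_indels", "mh_fraction_gt_threshold")
    rows = []
    for rep, label in zip(reports, labels):
        d = rep.to_dict() if hasattr(rep, "to_dict") else dict(rep)
        rows.append({"group": label, **{m: d.get(m) for m in metrics}})
    df = pd.DataFrame(rows)
    out = []
    for group, sub in df.groupby("group", sort=True):
        row = {"group": group, "n": len(sub)}
        for m in metrics:
            vals = pd.to_numeric(sub[m], errors="coerce")
            row[f"{m}_mean"] = vals.mean()
            row[f"{m}_sd"] = vals.std(ddof=1) if len(vals.dropna()) > 1 else np.nan
        out.append(row)
    return pd.DataFrame(out)
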