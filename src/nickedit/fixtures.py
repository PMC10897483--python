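"""Reproducible synthetic test bundles.

Each bundle is a reference set plus a simulated FASTQ/truth pair generated
at a pinned seed; the manifest records the generator parameters and SHA-256
checksums of every emitted file so that drift in the generator is caught.
Bundles are always regenerated from code, never hand-edited.

Standard bundles
----------------
``clean_wt``
    Error-free wildtype reads only; the pipeline must report zero editing.
``paired_nickase_mix``
    Heterogeneous paired-nickase spectrum: NHEJ indels, inter-nick
    deletions, MMEJ deletions, locus-templated insertions, vector
    insertions and complex alleles.
``nuclease_mix``
    Nuclease-style spectrum dominated by the perfect inter-nick deletion
    (59% of edited reads) with vector insertions.
``itr_hotspot``
    Vector-insertion-rich bundle for breakpoint-bias recovery.
``param_recovery``
    10,000 reads at 60% edited / 10% vector-chimeric, ITR-breakpoint bias
    0.8 and an equal 0/4/5 bp microhomology mix — the standard
    parameter-recovery condition.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from .errors import DataError
from .refio import write_references
from .simulate import SimConfig, build_synthetic_locus, build_synthetic_vector, simulate_dataset

BUNDLES: dict[str, dict] = {
    "clean_wt": {
        "locus_seed": 101, "vector_seed": 201,
        "sim": dict(n_reads=300, seed=301, sub_error_rate=0.0,
                    class_mix={"wildtype": 1.0}),
    },
    "paired_nickase_mix": {
        "locus_seed": 101, "vector_seed": 201,
        "sim": dict(n_reads=2000, seed=302),
    },
    "nuclease_mix": {
        "locus_seed": 101, "vector_seed": 201,
        "sim": dict(n_reads=2000, seed=303, class_mix={
            "wildtype": 0.30, "internick_deletion": 0.413,
            "nhej_indel": 0.127, "vector_insertion": 0.10,
            "templated_insertion": 0.06,
        }),
    },
    "itr_hotspot": {
        "locus_seed": 101, "vector_seed": 201,
        "sim": dict(n_reads=2000, seed=304, class_mix={
            "wildtype": 0.20, "vector_insertion": 0.80,
        }, itr_breakpoint_bias=0.8),
    },
    "param_recovery": {
        "locus_seed": 101, "vector_seed": 201,
        "sim": dict(n_reads=10000, seed=305, class_mix={
            "wildtype": 0.40, "vector_insertion": 0.10,
            "mmej_deletion": 0.50,
        }, itr_breakpoint_bias=0.8,
            mmej_mh_mix={0: 1 / 3, 4: 1 / 3, 5: 1 / 3}),
    },
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_fixture(name: str, target_dir, seed_offset: int = 0) -> dict:
    """Generate one named bundle under ``target_dir/name``; returns its
    manifest entry (parameters, seeds, file checksums and key paths)."""
    if name not in BUNDLES:
        raise DataError(f"unknown fixture {name!r}; known: {sorted(BUNDLES)}")
    spec = BUNDLES[name]
    out = Path(target_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    amplicon, pair = build_synthetic_locus(seed=spec["locus_seed"])
    vector = build_synthetic_vector(seed=spec["vector_seed"])
    ref_paths = write_references(out, amplicon, vector, pair)
    sim_kwargs = dict(spec["sim"])
    sim_kwargs["seed"] = sim_kwargs["seed"] + seed_offset
    cfg = SimConfig(**sim_kwargs)
    result = simulate_dataset(cfg, amplicon, vector, pair, out, prefix=name)
    files = sorted(
        [*(Path(p) for p in ref_paths.values()), *result.fastq, result.truth_path])
    return {
        "name": name,
        "locus_seed": spec["locus_seed"],
        "vector_seed": spec["vector_seed"],
        "sim": sim_kwargs,
        "class_counts": result.class_counts,
        "paths": {
            **{k: str(v) for k, v in ref_paths.items()},
            "reads": str(result.fastq[0]),
            "truth": str(result.truth_path),
        },
        "checksums": {p.name: _sha256(p) for p in files},
    }


def make_fixtures(target_dir, names=None, expect: dict | None = None) -> dict:
    """Generate the standard bundles; optionally verify against a previous
    manifest and fail naming the drifting fixture."""
    names = list(names or BUNDLES)
    manifest = {}
    for name in names:
        entry = make_fixture(name, target_dir)
        if expect is not None and name in expect:
            if expect[name]["checksums"] != entry["checksums"]:
                raise DataError(f"fixture {name!r}: checksum drift on regeneration")
        manifest[name] = entry
    path = Path(target_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
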