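"""End-to-end orchestration: manifest in, mined patterns and statistics out.

A manifest TSV (columns: interaction_id, pdb_path, chain_a, chain_b,
class_label) drives the full method: optional sequence-redundancy removal,
contact-bipartite construction with the accessibility filter, maximal
biclique mining with support counting, contrast classification between
class sets, and residue / residue-pair composition profiling. Every stage
writes its documented TSV/JSON output plus a machine-readable summary, and
every number in the summary is reproducible by calling the module
operations directly with the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import biclique, composition, interface_graph, patterns, redundancy
from .interface_graph import DWEBipartite
from .model import InteractionRecord
from .structure_io import chain_sequence, read_structure

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters, defaulting to the method's published values."""

    d_water: float = interface_graph.D_WATER          # 2.75 Å
    t_ra: float = interface_graph.T_RA                # 36 %
    p: int = biclique.P_MIN                           # 2
    q: int = biclique.Q_MIN                           # 3
    sup: int = biclique.SUP_MIN                       # 2
    ca_cutoff: float = interface_graph.CA_CUTOFF      # 6.0 Å
    similarity_threshold: float = redundancy.SIMILARITY_THRESHOLD  # 90 %
    ipr_hi: float = composition.IPR_HI                # 1.05
    ipr_lo: float = composition.IPR_LO                # 0.8
    iprp_log: float = composition.IPRP_LOG            # 1.05
    idr_k: int = composition.IDR_K                    # 7
    idrp_k: int = composition.IDRP_K                  # 10
    weighting: str = "per_supporting_interaction"
    asa_context: str = "complex"                      # or "isolated"
    min_atom_pairs: int = 1
    n_sphere_points: int = 960
    dedupe: bool = False
    seed: int = 0
    contrast_positive: Tuple[str, ...] = ("obligate", "non_obligate")
    contrast_negative: Tuple[str, ...] = ("crystal_packing",)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat TOML key-value file; keyword overrides win."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("contrast_positive", "contrast_negative"):
            if key in raw:
                raw[key] = tuple(raw[key])
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["contrast_positive"] = list(self.contrast_positive)
        d["contrast_negative"] = list(self.contrast_negative)
        return d


def read_manifest(path: str | Path) -> List[Dict[str, str]]:
    """Manifest TSV rows (header optional, columns fixed)."""
    rows = []
    base = Path(path).parent
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "interaction_id":  # header row
                continue
            if len(parts) != 5:
                raise ValueError(f"manifest row needs 5 columns, got {len(parts)}: {line!r}")
            interaction_id, pdb_path, chain_a, chain_b, class_label = parts
            p = Path(pdb_path)
            if not p.is_absolute():
                p = base / p
            rows.append(
                dict(interaction_id=interaction_id, pdb_path=str(p),
                     chain_a=chain_a, chain_b=chain_b, class_label=class_label)
            )
    if not rows:
        raise ValueError(f"empty manifest: {path}")
    return rows


def load_interactions(rows: Sequence[Dict[str, str]]) -> Tuple[List[InteractionRecord], int]:
    """Parse structures for the manifest rows; failures are logged and
    skipped, with the skip count returned."""
    records, failures = [], 0
    for row in rows:
        try:
            struct = read_structure(row["pdb_path"])
            records.append(
                InteractionRecord(
                    interaction_id=row["interaction_id"],
                    structure=struct,
                    chain_a=row["chain_a"],
                    chain_b=row["chain_b"],
                    class_label=row["class_label"],
                )
            )
        except Exception:
            logger.exception("failed to load interaction %s", row["interaction_id"])
            failures += 1
    return records, failures


def dedupe_interactions(
    records: Sequence[InteractionRecord], s: float
) -> Tuple[List[InteractionRecord], List[Tuple[str, str]]]:
    """Per-class greedy redundancy removal on chain sequences."""
    retained: List[InteractionRecord] = []
    removed_all: List[Tuple[str, str]] = []
    by_class: Dict[str, List[InteractionRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.class_label, []).append(rec)
    for class_records in by_class.values():
        pairs = [
            redundancy.ChainPairSeqs(
                rec.interaction_id,
                chain_sequence(rec.structure, rec.chain_a),
                chain_sequence(rec.structure, rec.chain_b),
            )
            for rec in class_records
        ]
        kept, removed = redundancy.remove_redundant_pairs(pairs, s)
        kept_ids = {p.pair_id for p in kept}
        retained.extend(r for r in class_records if r.interaction_id in kept_ids)
        removed_all.extend(removed)
    retained.sort(key=lambda r: [x.interaction_id for x in records].index(r.interaction_id))
    return retained, removed_all


def build_bipartites(
    records: Sequence[InteractionRecord], config: RunConfig
) -> List[DWEBipartite]:
    return [
        interface_graph.build_dwe_bipartite(
            rec,
            d_water=config.d_water,
            t_ra=config.t_ra,
            min_atom_pairs=config.min_atom_pairs,
            asa_context=config.asa_context,
            n_sphere_points=config.n_sphere_points,
        )
        for rec in records
    ]


def run_pipeline(
    manifest: str | Path,
    config: Optional[RunConfig] = None,
    out_dir: str | Path | None = None,
) -> Dict:
    """Execute the full method and return (and optionally write) the summary."""
    config = config or RunConfig()
    rows = read_manifest(manifest)
    records, n_failed = load_interactions(rows)
    if not records:
        raise ValueError("no loadable interactions in the manifest")

    removed: List[Tuple[str, str]] = []
    if config.dedupe:
        records, removed = dedupe_interactions(records, config.similarity_threshold)

    graphs = build_bipartites(records, config)
    class_labels = {r.interaction_id: r.class_label for r in records}
    mined = biclique.mine_frequent_patterns(
        graphs, class_labels, p=config.p, q=config.q, sup=config.sup
    )

    present_classes = sorted({r.class_label for r in records})
    summary: Dict = {
        "config": config.to_dict(),
        "n_interactions": len(records),
        "n_failed": n_failed,
        "n_removed_redundant": len(removed),
        "n_nonempty_bipartites": sum(1 for g in graphs if not g.is_empty()),
        "n_frequent_patterns": len(mined),
        "patterns": [
            {
                "key": rec.pattern.canonical_key,
                "support_by_class": rec.support_by_class,
                "supporting_ids": rec.supporting_ids,
            }
            for rec in mined
        ],
        "classes_present": present_classes,
    }

    pos = [c for c in config.contrast_positive if c in present_classes]
    neg = [c for c in config.contrast_negative if c in present_classes]
    if pos and neg:
        crecs = patterns.contrast_records(mined, pos, neg)
        summary["contrast"] = {
            "positive": pos,
            "negative": neg,
            "n_records": len(crecs),
            "n_unique_positive": sum(1 for r in crecs if r.is_unique and r.s_pos > 0),
            "n_unique_negative": sum(1 for r in crecs if r.is_unique and r.s_neg > 0),
            "bins": patterns.classify_and_bin(crecs).to_dict(),
        }
    else:
        logger.info("contrast stage skipped: need classes on both sides "
                    "(positive=%s, negative=%s)", pos, neg)
        summary["contrast"] = None

    summary["composition"] = {}
    for label in present_classes:
        try:
            profile = composition.CompositionProfile.from_support_records(
                mined, label,
                weighting=config.weighting,
                idr_k=config.idr_k, idrp_k=config.idrp_k,
                ipr_hi=config.ipr_hi, ipr_lo=config.ipr_lo,
                iprp_log=config.iprp_log,
            )
        except composition.UndefinedProfileError:
            summary["composition"][label] = None
            continue
        summary["composition"][label] = json.loads(profile.selections_json())

    if out_dir is not None:
        _write_outputs(Path(out_dir), summary, graphs, mined, records, config)
    return summary


def _write_outputs(out_dir, summary, graphs, mined, records, config):
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    params = {"d_water": config.d_water, "t_ra": config.t_ra}
    bip_text = "".join(
        interface_graph.serialize_bipartite(g, params) for g in graphs if not g.is_empty()
    )
    (out_dir / "bipartites.tsv").write_text(bip_text)
    classes = sorted({r.class_label for r in records})
    (out_dir / "patterns.tsv").write_text(biclique.support_records_tsv(mined, classes))
    logger.info("wrote outputs to %s", out_dir)
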