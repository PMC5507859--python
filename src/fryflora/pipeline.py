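"""End-to-end orchestration: QC -> normalization -> diversity -> comparisons.

``run_all`` executes the full analysis on a count table plus metadata and
writes every module's tabular output, a GraphML network per developmental
stage, and a JSON manifest (package version, seeds, input hashes, output
list) into a single run directory.  Re-running with an identical
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from . import conetwork, metrics, mucus_core, recruitment
from .permanova import permanova as _permanova
from .tables import (
    SampleRecord, Stage, STAGE_ORDER, TaxonomyMap,
    filter_otus, filter_samples, pool_replicates, pooled_records,
    read_count_table, read_metadata, write_count_table, write_metadata,
)

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger(__name__)

#: PERMANOVA comparisons of the standard study design
_COMPARISONS = (
    ("fry_pre_vs_fry_mucus", ("fry", Stage.PRE), ("fry", Stage.MUCUS)),
    ("fry_post_early_vs_fry_post_late", ("fry", Stage.POST_EARLY), ("fry", Stage.POST_LATE)),
    ("fry_post_early_vs_adult_feces", ("fry", Stage.POST_EARLY), ("niche", "adult_feces")),
    ("fry_post_late_vs_adult_feces", ("fry", Stage.POST_LATE), ("niche", "adult_feces")),
    ("breeding_vs_nonbreeding_mucus", ("niche", "breeding_mucus"), ("niche", "nonbreeding_mucus")),
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (all thresholds in one place)."""

    table_path: str
    metadata_path: str
    out_dir: str
    taxonomy_path: str | None = None
    table_format: str = "tsv_wide"
    min_depth: int = 500
    min_total_reads: int = 50
    min_otu_samples: int = 2
    css_percentile: float = 0.5
    n_permutations: int = 10000
    network_k: int = 50
    rho_min: float = 0.9
    alpha_adj: float = 1e-4
    direction: str = "fry_over_reservoir"
    include_day0: bool = True
    pair_mode: str = "abundance_weighted"
    n_random_pairs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.css_percentile <= 1:
            raise ValueError("css_percentile must lie in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 <= self.rho_min <= 1 or not 0 < self.alpha_adj <= 1:
            raise ValueError("network thresholds out of range")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _group_columns(records: Sequence[SampleRecord], rel_columns, kind, value) -> list[str]:
    cols = []
    for r in records:
        if r.sample_id not in rel_columns:
            continue
        if kind == "niche" and r.niche == value:
            cols.append(r.sample_id)
        elif kind == "fry" and r.stage is value:
            cols.append(r.sample_id)
    return cols


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "fryflora_version": __version__,
        "config": asdict(cfg),
        "inputs": {},
        "outputs": [],
        "stages_completed": [],
    }

    def emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return out / name

    for key in ("table_path", "metadata_path", "taxonomy_path"):
        path = getattr(cfg, key)
        if path:
            p = Path(path)
            if not p.exists():
                raise FileNotFoundError(f"{key}: {path}")
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(p)}

    table = read_count_table(cfg.table_path, cfg.table_format)
    meta = read_metadata(cfg.metadata_path)
    taxonomy = TaxonomyMap.from_tsv(cfg.taxonomy_path) if cfg.taxonomy_path else None

    # QC: pool replicates, drop shallow samples, drop low-information OTUs
    pooled = pool_replicates(table, meta)
    pmeta = pooled_records(meta)
    qc = filter_otus(
        filter_samples(pooled, cfg.min_depth),
        cfg.min_total_reads, cfg.min_otu_samples,
    )
    pmeta = [r for r in pmeta if r.sample_id in qc.sample_ids]
    write_count_table(qc, emit("qc_counts.tsv"))
    write_metadata(pmeta, emit("qc_metadata.tsv"))
    manifest["stages_completed"].append("qc")

    # alpha diversity on raw pooled counts (integer estimators)
    alpha = metrics.alpha_table(qc)
    alpha.to_csv(emit("alpha_diversity.tsv"), sep="\t")
    manifest["stages_completed"].append("alpha")

    # CSS normalization; community analyses on the re-closed proportions
    css = metrics.css_fit(qc, cfg.css_percentile)
    normalized = metrics.css_apply(qc, css)
    normalized.to_csv(emit("css_normalized.tsv"), sep="\t")
    rel = normalized / normalized.sum(axis=0)
    manifest["stages_completed"].append("normalize")

    dm = metrics.distance_matrix(rel)
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        emit("thetayc_distance.tsv"), sep="\t")
    manifest["stages_completed"].append("beta")

    # group dissimilarity summaries + PERMANOVA comparisons
    summaries, perm_rows = [], []
    for label, spec_a, spec_b in _COMPARISONS:
        a = _group_columns(pmeta, rel.columns, *spec_a)
        b = _group_columns(pmeta, rel.columns, *spec_b)
        if not a or not b:
            continue
        s = metrics.summarize_group_dissimilarity(dm, a, b, label=label)
        summaries.append(asdict(s))
        if len(a) >= 2 and len(b) >= 2:
            sub = dm.filter(a + b)
            labels = {s_: ("A" if s_ in a else "B") for s_ in sub.ids}
            res = _permanova(sub, labels, n_perm=cfg.n_permutations,
                             seed=cfg.seed)
            perm_rows.append({
                "comparison": label,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "df_total": res.n_samples - 1,
                "pseudo_F": res.pseudo_f,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            })
    pd.DataFrame(summaries).to_csv(emit("group_dissimilarity.tsv"), sep="\t",
                                   index=False)
    pd.DataFrame(perm_rows).to_csv(emit("permanova.tsv"), sep="\t", index=False)
    manifest["stages_completed"].append("permanova")

    # recruitment screen + transmission candidates + source attribution
    screen = recruitment.recruitment_screen(
        rel, pmeta, direction=cfg.direction, include_day0=cfg.include_day0)
    screen.to_csv(emit("recruitment.tsv"), sep="\t", index=False)

    by_niche: dict[str, list[str]] = {}
    for r in pmeta:
        by_niche.setdefault(r.niche, []).append(r.sample_id)
    wl_cols = [r.sample_id for r in pmeta
               if r.niche == "whole_fry" and r.stage is Stage.MUCUS]
    water_cols = by_niche.get("water", [])
    bdm_cols = by_niche.get("breeding_mucus", [])
    nbdm_cols = by_niche.get("nonbreeding_mucus", [])
    candidates = []
    if wl_cols and bdm_cols and water_cols:
        candidates = recruitment.transmission_candidates(
            rel[wl_cols], rel[bdm_cols], qc.subset(samples=water_cols),
            nonbreeding_mucus=rel[nbdm_cols] if nbdm_cols else None,
            taxonomy=taxonomy,
        )
    pd.DataFrame([asdict(c) for c in candidates]).to_csv(
        emit("transmission_candidates.tsv"), sep="\t", index=False)

    attribution_rows = []
    fry_late = [r.sample_id for r in pmeta
                if r.niche == "fry_feces" and r.stage is Stage.POST_LATE]
    if fry_late:
        sources = {}
        for label, cols in (("breeding_mucus", bdm_cols),
                            ("adult_diet", by_niche.get("adult_diet", [])),
                            ("water", water_cols)):
            if cols:
                sources[label] = rel[cols]
        for otu in conetwork.top_k_otus(rel[fry_late], k=20):
            call = recruitment.most_abundant_source(otu, sources)
            attribution_rows.append({
                "otu_id": otu,
                "taxon": taxonomy.label(otu) if taxonomy else otu,
                "fry_post_late_pct": float(rel[fry_late].loc[otu].mean()) * 100,
                "source": call.source,
                "tie": call.tie,
                **{f"{k}_pct": v * 100 for k, v in call.means.items()},
            })
    pd.DataFrame(attribution_rows).to_csv(emit("source_attribution.tsv"),
                                          sep="\t", index=False)
    manifest["stages_completed"].append("recruit")

    # per-stage co-abundance networks (correlations over all samples)
    network = conetwork.build_network(rel, k=cfg.network_k, rho_min=cfg.rho_min,
                                      alpha_adj=cfg.alpha_adj, taxonomy=taxonomy)
    conetwork.export_network(network, emit("network_edges.tsv"), "edge_list_tsv")
    flagged = recruitment.significant_reservoirs(screen)
    for stage in STAGE_ORDER:
        reservoirs = flagged.get(stage.value) or []
        fry_cols = [r.sample_id for r in pmeta
                    if r.niche == recruitment.STAGE_FRY_NICHE[stage]
                    and r.stage is stage]
        if not fry_cols or not reservoirs:
            continue
        res_cols = [c for niche in recruitment.RESERVOIR_NICHES[reservoirs[0]]
                    for c in by_niche.get(niche, [])]
        if not res_cols:
            continue
        staged = conetwork.provenance_labels(network, rel[fry_cols], rel[res_cols])
        conetwork.export_network(staged, emit(f"network_{stage.value}.graphml"))
    manifest["stages_completed"].append("network")

    # parent mucus core: same-day breeding pairs + random control baseline
    sharing_rows = []
    bdm_by_day: dict[int | None, list[str]] = {}
    for r in pmeta:
        if r.niche == "breeding_mucus":
            bdm_by_day.setdefault(r.dph, []).append(r.sample_id)
    for day, cols in sorted(bdm_by_day.items(), key=lambda kv: (kv[0] is None, kv[0])):
        for a, b in zip(cols[::2], cols[1::2]):
            sharing_rows.append(asdict(mucus_core.PairSharing(
                pair=(a, b), period="during_MF", mode=cfg.pair_mode,
                shared_value=mucus_core.pair_shared_fraction(
                    rel[a], rel[b], cfg.pair_mode),
            )))
    if len(nbdm_cols) >= 2:
        for p in mucus_core.random_pair_baseline(
                rel[nbdm_cols], n_pairs=cfg.n_random_pairs, seed=cfg.seed,
                mode=cfg.pair_mode):
            sharing_rows.append(asdict(p))
    pd.DataFrame(sharing_rows).to_csv(emit("mucus_sharing.tsv"), sep="\t",
                                      index=False)
    shifts = []
    if bdm_cols and nbdm_cols:
        shifts = mucus_core.taxonomic_shift(rel[bdm_cols], rel[nbdm_cols],
                                            top_n=20, taxonomy=taxonomy)
    pd.DataFrame([asdict(s) for s in shifts]).to_csv(
        emit("taxonomic_shift.tsv"), sep="\t", index=False)
    manifest["stages_completed"].append("mucus")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["outputs"].append("manifest.json")
    return manifest
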