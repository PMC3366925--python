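"""End-to-end pipeline: parse → TMA filter/dedup → classify → tables →
diversity → clade network → dating, with all artifacts written as text.

The stages mirror how a regional mtDNA survey is analyzed: the cohort is
reduced to autochthonous, maternally unrelated samples; haplotypes are
classified on a motif tree; regional frequency tables and a geographic
independence test summarize structure; diversity indices summarize the
sequences; and the focal clade (default: the 6-bp-deletion clade A2af) is
expanded into a median-joining network whose root age is estimated in
mutational units and converted to years.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd

from .classify import HaplogroupTree, chisq_independence, classify, frequency_table, AGGREGATES
from .dating import ClockConfig
from .diversity import diversity_stats
from .haplotypes import read_haplotype_table
from .network import build_character_matrix, median_joining, network_node_ages
from .pedigree import clusters_from_records, dedup_related, filter_by_tma, records_from_metadata

log = logging.getLogger("mtphylo")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; round-trips through ``key = value``."""

    haplotypes: str = ""
    metadata: str = ""
    tree: str = ""                 # empty -> bundled default tree
    outdir: str = "mtphylo_out"
    keep_tma: str = "Panama"
    focal_clade: str = "A2af"
    epsilon: int = 0
    years_per_mutation: float = 3624.0
    control_region_rate: float = 0.0   # 0 -> not configured
    clock_scale: str = "whole_molecule"
    filter_profile: str = "network"
    seed: int = 0
    simulate: bool = False
    verbosity: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dc_fields(cls)}
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dc_fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    def config_hash(self) -> str:
        payload = json.dumps(
            {f.name: getattr(self, f.name) for f in dc_fields(self)},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def clock(self) -> ClockConfig:
        return ClockConfig(
            years_per_mutation=self.years_per_mutation,
            control_region_rate=self.control_region_rate or None,
            label="configured",
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a result bundle (paths + key numbers)."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("seed=%d config_hash=%s", config.seed, config.config_hash())

    if config.simulate:
        from .simulate import SimConfig, simulate_cohort

        cohort = simulate_cohort(SimConfig(seed=config.seed))
        haps, metadata = cohort.haplotypes, cohort.metadata
        cohort.write(out / "simulated_haplotypes.tsv",
                     out / "simulated_metadata.tsv",
                     out / "simulated_truth.json")
    else:
        haps = read_haplotype_table(config.haplotypes)
        metadata = pd.read_csv(config.metadata, sep="\t", dtype=str,
                               keep_default_na=False)
    log.info("stage=input n=%d", len(haps))

    # --- pedigree: TMA filter then kin dedup -------------------------------
    records = records_from_metadata(metadata)
    kept, excluded = filter_by_tma(records, keep_origin=config.keep_tma)
    log.info("stage=tma kept=%d excluded=%s", len(kept), excluded)
    retained, removal_log = dedup_related(kept, clusters_from_records(kept))
    removal_log.to_csv(out / "dedup_removals.tsv", sep="\t", index=False)
    keep_ids = {r.sample_id for r in retained}
    haps = [h for h in haps if h.sample_id in keep_ids]
    metadata = metadata[metadata.sample_id.isin(keep_ids)]
    log.info("stage=dedup retained=%d removed=%d", len(haps), len(removal_log))

    # --- classification ----------------------------------------------------
    tree = (HaplogroupTree.from_file(config.tree) if config.tree
            else HaplogroupTree.bundled("default"))
    results = [classify(h, tree) for h in haps]
    cls_df = pd.DataFrame([vars(r) for r in results])
    cls_df.to_csv(out / "classification.tsv", sep="\t", index=False)

    table = frequency_table(results, metadata)
    table.to_csv(out / "frequency_table.tsv", sep="\t",
                 float_format="%.2f")
    chi = None
    kinds = metadata.set_index("sample_id")["region_kind"]
    origin_of = {}
    for r in results:
        for agg, members in AGGREGATES.items():
            if any(r.best_node.startswith(m) for m in members):
                origin_of[r.sample_id] = agg
                break
    crosstab = pd.crosstab(
        [kinds.get(r.sample_id, "province") for r in results],
        [origin_of.get(r.sample_id, "Native") for r in results],
    )
    if crosstab.shape[0] >= 2 and crosstab.shape[1] >= 2:
        chi = chisq_independence(crosstab)
        log.info("stage=chisq stat=%.3f df=%d p=%.2e", *chi)

    # --- diversity ----------------------------------------------------------
    stats = None
    if len(haps) >= 2:
        stats = diversity_stats(haps)
        pd.DataFrame([vars(stats)]).to_csv(out / "diversity.tsv", sep="\t",
                                           index=False)
    else:
        log.warning("stage=diversity skipped: fewer than two samples")

    # --- focal clade network + dating ---------------------------------------
    focal = [h for h, r in zip(haps, results)
             if r.best_node.startswith(config.focal_clade)]
    age = None
    if focal:
        from .haplotypes import Haplotype
        from .variants import NETWORK_FILTER, serialize_variant

        founder = Haplotype(
            sample_id="founder",
            variants=frozenset(
                v for v in tree.founding_variants(config.focal_clade)
                if focal[0].covered_range.contains_variant(v)
            ),
            covered_range=focal[0].covered_range,
        )
        matrix = build_character_matrix(focal, ancestor=founder)
        net = median_joining(matrix, epsilon=config.epsilon)
        net.write_gml(out / "network.gml")
        net.write_dot(out / "network.dot")
        net.node_table().to_csv(out / "network_nodes.csv", index=False)
        # root the dating at the clade founder's profile
        founder_tokens = {
            serialize_variant(v)
            for v in NETWORK_FILTER.apply(founder.variants, profile="network")
        }
        founder_profile = tuple(
            1 if c in founder_tokens else 0 for c in matrix.characters)
        root = next(
            n for n, d in net.graph.nodes(data=True)
            if d["profile"] == founder_profile
        )
        age = network_node_ages(net, root, config.clock(),
                                scale=config.clock_scale)
        pd.DataFrame([vars(age)]).to_csv(out / "ages.tsv", sep="\t", index=False)
        log.info("stage=dating clade=%s rho=%.3f age=%.0f",
                 config.focal_clade, age.rho, age.age_years)
    else:
        log.warning("stage=network skipped: no %s samples", config.focal_clade)

    return {
        "outdir": str(out),
        "n_final": len(haps),
        "n_removed_related": int(len(removal_log)),
        "tma_excluded": excluded,
        "frequency_table": table,
        "chisq": chi,
        "diversity": stats,
        "focal_age": age,
        "artifacts": sorted(p.name for p in out.iterdir()),
    }
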