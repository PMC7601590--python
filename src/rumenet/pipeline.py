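"""End-to-end orchestration: simulate -> preprocess -> diversity ->
ordination -> network -> differential abundance.

Every stage writes plain TSV/JSON/GraphML under the run directory and is
recorded in a manifest (stage, seed, parameters, output hashes), so any
stage can be re-run and audited independently.  All randomness derives
from one master seed; no stage touches global random state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import diffabund as da
from . import diversity as dv
from . import network as nw
from . import ordination as ord_
from . import preprocess as pp
from . import synthetic as syn
from . import tables_io as tio
from .tables_io import Bloat, Treatment

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run (YAML-loadable)."""

    # either paths to existing tables ...
    fungal_path: Optional[str] = None
    bacterial_path: Optional[str] = None
    metadata_path: Optional[str] = None
    # ... or a simulate block (kwargs of SyntheticConfig)
    simulate: Optional[dict] = None

    taxonomy_keep: str = "Neocallimastigomycota"
    rarefy_depth_fungal: int = 7000
    rarefy_depth_bacterial: int = 25000
    prevalence_network: float = 0.50
    prevalence_diffabund: float = 0.10
    alpha: float = 0.05
    min_support: int = 3
    ci_level: float = 0.95
    b_perm: int = 1000
    b_boot: int = 1000
    b_diffabund: int = 4999
    n_perm_ordination: int = 999
    hub_k: int = 4
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.prevalence_network <= 1:
            raise ValueError("prevalence_network must be in (0, 1]")
        if not 0 < self.prevalence_diffabund <= 1:
            raise ValueError("prevalence_diffabund must be in (0, 1]")
        if self.rarefy_depth_fungal < 1 or self.rarefy_depth_bacterial < 1:
            raise ValueError("rarefaction depths must be >= 1")
        has_paths = all(
            (self.fungal_path, self.bacterial_path, self.metadata_path)
        )
        if not has_paths and self.simulate is None:
            raise ValueError("config needs input paths or a simulate block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the complete analysis; returns the manifest dictionary."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 6)
    manifest: dict = {"master_seed": config.seed, "stages": []}

    def record(stage: str, seed: int, params: dict, outputs: Sequence[Path]):
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": seed,
                "params": params,
                "outputs": {p.name: _sha256(p) for p in outputs},
            }
        )

    # ------------------------------------------------------------------ input
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs["seed"] = seeds[0]
        scfg = syn.SyntheticConfig(**sim_kwargs)
        fungal, bacterial, meta, truth = syn.generate_dataset(scfg)
        tio.write_count_table(fungal, out / "fungal_counts.tsv")
        tio.write_count_table(bacterial, out / "bacterial_counts.tsv")
        tio.write_metadata(meta, out / "metadata.tsv")
        truth.to_json(out / "truth.json")
        record(
            "simulate", seeds[0],
            {k: v for k, v in sim_kwargs.items() if k != "treatment_effects"},
            [out / "fungal_counts.tsv", out / "bacterial_counts.tsv",
             out / "metadata.tsv", out / "truth.json"],
        )
    else:
        for p in (config.fungal_path, config.bacterial_path, config.metadata_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
        fungal = tio.read_count_table(config.fungal_path)
        bacterial = tio.read_count_table(config.bacterial_path)
        meta = tio.read_metadata(config.metadata_path)

    # ------------------------------------------------------------- preprocess
    fungal_f = pp.filter_taxonomy(fungal, config.taxonomy_keep)
    fungal_r = pp.rarefy(fungal_f, config.rarefy_depth_fungal, seed=seeds[1])
    bacterial_r = pp.rarefy(bacterial, config.rarefy_depth_bacterial, seed=seeds[1] + 1)
    tio.write_count_table(fungal_r, out / "fungal_rarefied.tsv")
    tio.write_count_table(bacterial_r, out / "bacterial_rarefied.tsv")
    record(
        "preprocess", seeds[1],
        {
            "taxonomy_keep": config.taxonomy_keep,
            "depth_fungal": config.rarefy_depth_fungal,
            "depth_bacterial": config.rarefy_depth_bacterial,
        },
        [out / "fungal_rarefied.tsv", out / "bacterial_rarefied.tsv"],
    )

    by_id = {m.sample_id: m for m in meta}

    # -------------------------------------------------------------- diversity
    alpha_f = dv.alpha_diversity_table(fungal_r)
    alpha_b = dv.alpha_diversity_table(bacterial_r)
    alpha_tab = alpha_f.join(alpha_b, lsuffix="_fungal", rsuffix="_bacterial",
                             how="outer")
    alpha_tab.to_csv(out / "alpha_diversity.tsv", sep="\t")

    div_rows = []
    for index in ("chao1", "shannon"):
        vals = alpha_f[index].to_dict()
        base = dv.pair_by_steer(
            vals, meta, lambda m: m.treatment is Treatment.BASELINE
        )
        for treat in (Treatment.PA, Treatment.AA, Treatment.AS):
            grp = dv.pair_by_steer(
                vals, meta, lambda m, t=treat: m.treatment is t
            )
            try:
                w, p = dv.wilcoxon_signed_rank(grp, base)
            except ValueError as err:
                w, p = np.nan, np.nan
                logger.warning("diversity contrast %s: %s", treat.value, err)
            div_rows.append(
                {"index": index, "contrast": f"{treat.value} vs BASELINE",
                 "statistic": w, "p": p}
            )
    # fungal vs bacterial diversity correlation on shared samples
    shared = [s for s in alpha_f.index if s in alpha_b.index]
    rho, rho_p = dv.spearman_correlation(
        alpha_f.loc[shared, "shannon"], alpha_b.loc[shared, "shannon"]
    )
    div_tests = pd.DataFrame(div_rows)
    div_tests.to_csv(out / "diversity_tests.tsv", sep="\t", index=False)
    record(
        "diversity", 0, {"rho_fungal_bacterial": rho, "rho_p": rho_p},
        [out / "alpha_diversity.tsv", out / "diversity_tests.tsv"],
    )

    # -------------------------------------------------------------- ordination
    comp_f = pp.replace_zeros_bayesian(
        pp.filter_prevalence(fungal_r, config.prevalence_network)
    )
    clr_f = pp.clr_transform(comp_f)
    treat_labels = np.asarray(
        [by_id[s].treatment.value for s in clr_f.sample_ids]
    )
    rda_res = ord_.rda(
        clr_f, treat_labels, n_perm=config.n_perm_ordination, seed=seeds[2]
    )
    bc = ord_.bray_curtis_matrix(
        pp.filter_prevalence(fungal_r, config.prevalence_network)
    )
    pairwise = ord_.pairwise_permanova(
        bc,
        [by_id[s].treatment.value for s in fungal_r.sample_ids],
        n_perm=config.n_perm_ordination,
        seed=seeds[2] + 1,
    )
    pairwise.to_csv(out / "permanova_pairwise.tsv", sep="\t", index=False)
    ord_summary = {
        "rda_treatment": dataclasses.asdict(rda_res),
    }
    record("ordination", seeds[2], ord_summary,
           [out / "permanova_pairwise.tsv"])

    # ---------------------------------------------------------------- network
    strata = nw.stratify_samples(
        meta, [s for s in fungal_r.sample_ids if s in set(bacterial_r.sample_ids)]
    )
    networks: dict[str, nw.CoNetwork] = {}
    net_summary: dict = {}
    for si, (stratum, samples) in enumerate(strata.items()):
        if len(samples) < 8:
            logger.warning("stratum %s has %d samples; skipped", stratum,
                           len(samples))
            continue
        f_sub = fungal_r.select_samples(
            [fungal_r.sample_ids.index(s) for s in samples]
        )
        b_sub = bacterial_r.select_samples(
            [bacterial_r.sample_ids.index(s) for s in samples]
        )
        inp = nw.prepare_network_input(
            f_sub, b_sub, min_prevalence=config.prevalence_network
        )
        net = nw.infer_network(
            inp,
            b_perm=config.b_perm,
            b_boot=config.b_boot,
            alpha=config.alpha,
            min_support=config.min_support,
            ci_level=config.ci_level,
            seed=seeds[3] + si,
            stratum=stratum,
        )
        networks[stratum] = net
        tag = stratum.replace("-", "_")
        tio.write_edge_list(net.edges, out / f"edges_{tag}.tsv")
        tio.write_graphml(net.edges, out / f"network_{tag}.graphml",
                          kingdom_of=net.nodes)
        net_summary[stratum] = {
            "n_samples": len(samples),
            "n_candidates": net.n_candidates,
            "n_edges": len(net.edges),
            "exclusion_fraction": (
                nw.exclusion_fraction(net) if net.edges else None
            ),
            "hubs": nw.find_hubs(net, config.hub_k) if net.edges else [],
        }
    hubs = nw.hub_union(networks.values(), k=config.hub_k)
    net_summary["hub_union"] = hubs
    (out / "network_summary.json").write_text(json.dumps(net_summary, indent=2))
    hub_rows = [
        {"taxon": t, "stratum": s}
        for s, net in networks.items()
        for t in nw.find_hubs(net, config.hub_k)
        if net.edges
    ]
    pd.DataFrame(hub_rows, columns=["taxon", "stratum"]).to_csv(
        out / "hubs.tsv", sep="\t", index=False
    )
    record(
        "network", seeds[3],
        {"b_perm": config.b_perm, "b_boot": config.b_boot,
         "min_support": config.min_support, "alpha": config.alpha},
        sorted(out.glob("edges_*.tsv")) + [out / "network_summary.json",
                                           out / "hubs.tsv"],
    )

    # ------------------------------------------- hub RDA on bacterial community
    fungal_hubs = [t for t in hubs if t in set(fungal_r.taxon_ids)]
    hub_rda = None
    if fungal_hubs:
        comp_b = pp.replace_zeros_bayesian(
            pp.filter_prevalence(bacterial_r, config.prevalence_network)
        )
        clr_b = pp.clr_transform(comp_b)
        shared_s = [s for s in clr_b.sample_ids if s in set(clr_f.sample_ids)]
        comp_fh = pp.replace_zeros_bayesian(fungal_r)
        clr_fh = pp.clr_transform(comp_fh)
        hub_X = np.column_stack(
            [
                np.asarray(clr_fh.values)[
                    [clr_fh.sample_ids.index(s) for s in shared_s],
                    clr_fh.taxon_ids.index(t),
                ]
                for t in fungal_hubs
            ]
        )
        Yb = np.asarray(clr_b.values)[
            [clr_b.sample_ids.index(s) for s in shared_s]
        ]
        cond = np.asarray(
            [
                f"{by_id[s].treatment.value}/{by_id[s].bloat.value}"
                for s in shared_s
            ]
        )
        try:
            hub_rda = ord_.rda(
                Yb, hub_X, condition=cond,
                n_perm=config.n_perm_ordination, seed=seeds[4],
            )
        except ValueError as err:
            logger.warning("hub RDA skipped: %s", err)
    if hub_rda is not None:
        ord_summary["rda_hubs_partial"] = dataclasses.asdict(hub_rda)
    (out / "ordination_summary.json").write_text(
        json.dumps(ord_summary, indent=2)
    )

    # -------------------------------------------------------------- diffabund
    dres = da.run_diffabund(
        fungal_r, meta,
        min_prevalence=config.prevalence_diffabund,
        b=config.b_diffabund,
        seed=seeds[5],
        alpha=config.alpha,
    )
    dres.per_taxon.to_csv(out / "diffabund_per_taxon.tsv", sep="\t")
    followup = da.pairwise_followup(dres, meta)
    followup.to_csv(out / "diffabund_pairwise.tsv", sep="\t", index=False)
    record(
        "diffabund", seeds[5],
        {"b": config.b_diffabund, "min_prevalence": config.prevalence_diffabund,
         "n_flagged": len(dres.flagged)},
        [out / "diffabund_per_taxon.tsv", out / "diffabund_pairwise.tsv"],
    )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
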