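"""Synthetic paired fungal/bacterial ASV datasets for the crossover grazing design.

The generator emulates the statistical structure the downstream analysis
assumes: 12 steers sampled once on a hay baseline and once per pasture
period of a 3x3 crossover (pure alfalfa / alfalfa+Alfasure /
alfalfa+sainfoin), compositional sparse counts from a logistic-normal +
multinomial model, separate ITS and 16S sequencing depths, treatment
shifts on latent log-abundance, and planted fungus-bacterium couplings
expressed as shared latent factors so that their sign and strength are
controllable.  Each hub fungus owns one standard-normal per-sample
factor; the hub loads ``+c`` on it and every planted bacterial partner
loads ``sign * c``, making the hub a genuine shared driver of its
partners.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .tables_io import Bloat, CountTable, SampleMetadata, Treatment

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_dataset", "null_dataset"]

#: anaerobic rumen fungal genera used for fungal lineage strings
_ARF_GENERA = [
    "Neocallimastix", "Caecomyces", "Orpinomyces", "Piromyces",
    "Cyllamyces", "Anaeromyces", "Buwchfawromyces", "Neocallimastigaceae_unclassified",
]
_OFFTARGET_PHYLA = ["Ascomycota", "Basidiomycota"]
_BACT_PHYLA = [
    "Bacteroidetes", "Firmicutes", "Fibrobacteres", "Spirochaetes", "Proteobacteria",
]

_GRAZING = [Treatment.PA, Treatment.AA, Treatment.AS]


class SyntheticConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    Defaults reproduce the study conditions: 12 steers, a baseline
    occasion plus a 3x3 crossover, four missing grazing samples (one PA,
    two AA, one AS, giving n = 44), per-sample read totals matching the
    reported ITS / 16S library sizes, and mostly-negative planted
    couplings (``coupling_sign_mix = 0.8``).
    """

    n_steers: int = 12
    n_fungal_taxa: int = 30          # target-phylum (Neocallimastigomycota) taxa
    n_offtarget_fungi: int = 6       # Ascomycota/Basidiomycota taxa, removed by the phylum filter
    n_bacterial_taxa: int = 120
    # lognormal (meanlog, sdlog) of per-sample read totals
    depth_fungal: tuple[float, float] = (float(np.log(95_000.0)), 0.55)
    depth_bacterial: tuple[float, float] = (float(np.log(52_650.0)), 0.33)
    n_hubs: int = 5
    partners_per_hub: int = 8
    coupling_strength: float = 1.5
    coupling_sign_mix: float = 0.8   # fraction of negative (exclusion) couplings
    # taxon-group -> per-treatment log-fold shift; None -> drawn from the model below
    treatment_effects: Optional[dict[str, dict[str, float]]] = None
    responsive_fraction: float = 0.3
    treatment_effect_sd: float = 1.0
    treatment_effect_within_sd: float = 0.3
    steer_sd: float = 0.3
    noise_sd: float = 0.3
    base_sd: float = 1.5
    planted_base_mean: float = 0.5
    planted_base_sd: float = 0.5
    dropout_extra: float = 0.05
    # number of missing grazing samples per treatment (study pattern: 1 PA, 2 AA, 1 AS)
    missing_per_treatment: dict[str, int] = field(
        default_factory=lambda: {"PA": 1, "AA": 2, "AS": 1}
    )
    # P(bloat) per grazing treatment (baseline is always NA)
    bloat_prob: dict[str, float] = field(
        default_factory=lambda: {"PA": 1.0, "AA": 0.0, "AS": 6.0 / 11.0}
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_steers", "n_fungal_taxa", "n_bacterial_taxa"):
            if getattr(self, name) <= 0:
                raise SyntheticConfigError(f"{name} must be positive")
        if self.n_offtarget_fungi < 0:
            raise SyntheticConfigError("n_offtarget_fungi must be >= 0")
        if not 0.0 <= self.coupling_sign_mix <= 1.0:
            raise SyntheticConfigError("coupling_sign_mix must be in [0, 1]")
        if self.coupling_strength < 0:
            raise SyntheticConfigError("coupling_strength must be >= 0")
        if self.n_hubs * self.partners_per_hub > self.n_bacterial_taxa:
            raise SyntheticConfigError(
                "n_hubs * partners_per_hub exceeds the number of bacterial taxa"
            )
        if self.n_hubs > self.n_fungal_taxa:
            raise SyntheticConfigError("more hubs than fungal taxa")


@dataclass
class SyntheticTruth:
    """Planted structure of a generated dataset, for recovery scoring."""

    planted_edges: list[tuple[str, str, int]]  # (fungal, bacterial, sign in {-1,+1})
    group_effects: dict[str, dict[str, float]]  # taxon -> treatment -> latent shift
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "planted_edges": [list(e) for e in self.planted_edges],
                    "group_effects": self.group_effects,
                    "seed": self.seed,
                },
                indent=2,
            )
        )


def _design(cfg: SyntheticConfig, rng: np.random.Generator) -> list[SampleMetadata]:
    """Baseline occasion + 3x3 crossover with study-pattern missing samples."""
    steers = [f"S{i + 1:02d}" for i in range(cfg.n_steers)]
    # Latin-square sequences over the three grazing treatments
    seqs = [
        [Treatment.PA, Treatment.AA, Treatment.AS],
        [Treatment.AA, Treatment.AS, Treatment.PA],
        [Treatment.AS, Treatment.PA, Treatment.AA],
    ]
    occasions: list[tuple[str, int, Treatment]] = []
    for i, steer in enumerate(steers):
        occasions.append((steer, 0, Treatment.BASELINE))
        for period in (1, 2, 3):
            occasions.append((steer, period, seqs[i % 3][period - 1]))

    # drop the configured number of grazing samples per treatment
    dropped: set[tuple[str, int]] = set()
    for treat_name, n_missing in (cfg.missing_per_treatment or {}).items():
        treat = Treatment(treat_name)
        candidates = [
            (s, p) for (s, p, t) in occasions if t is treat and p > 0
        ]
        if n_missing > len(candidates):
            raise SyntheticConfigError(
                f"cannot drop {n_missing} samples from treatment {treat_name}"
            )
        idx = rng.choice(len(candidates), size=n_missing, replace=False)
        dropped.update(candidates[i] for i in idx)

    records: list[SampleMetadata] = []
    for steer, period, treat in occasions:
        if (steer, period) in dropped:
            continue
        if treat is Treatment.BASELINE:
            bloat = Bloat.NA
        else:
            p_b = float((cfg.bloat_prob or {}).get(treat.value, 0.5))
            bloat = Bloat.B if rng.random() < p_b else Bloat.NB
        records.append(
            SampleMetadata(
                sample_id=f"{steer}.P{period}",
                steer_id=steer,
                period=period,
                treatment=treat,
                bloat=bloat,
            )
        )
    return records


def _fungal_taxonomy(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    ids, lineages = [], []
    for i in range(cfg.n_fungal_taxa):
        genus = _ARF_GENERA[i % len(_ARF_GENERA)]
        ids.append(f"F{i:03d}")
        lineages.append(
            "k__Fungi;p__Neocallimastigomycota;c__Neocallimastigomycetes;"
            f"o__Neocallimastigales;f__Neocallimastigaceae;g__{genus}"
        )
    for j in range(cfg.n_offtarget_fungi):
        phylum = _OFFTARGET_PHYLA[j % len(_OFFTARGET_PHYLA)]
        ids.append(f"F{cfg.n_fungal_taxa + j:03d}")
        lineages.append(f"k__Fungi;p__{phylum};c__;o__;f__;g__")
    return ids, lineages


def _bacterial_taxonomy(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    ids, lineages = [], []
    for i in range(cfg.n_bacterial_taxa):
        phylum = _BACT_PHYLA[i % len(_BACT_PHYLA)]
        ids.append(f"B{i:03d}")
        lineages.append(f"k__Bacteria;p__{phylum};c__;o__;f__;g__")
    return ids, lineages


def _draw_treatment_effects(
    cfg: SyntheticConfig,
    taxon_ids: list[str],
    rng: np.random.Generator,
) -> dict[str, dict[str, float]]:
    """Per-taxon latent shifts for the grazing treatments (baseline = 0).

    A ``responsive_fraction`` of taxa respond to the hay -> pasture diet
    change with a shared alfalfa shift plus smaller treatment-specific
    deviations, mirroring a community reorganisation that is mostly about
    diet with secondary preventive-treatment effects.
    """
    if cfg.treatment_effects is not None:
        return {
            t: {k: float(v) for k, v in shifts.items()}
            for t, shifts in cfg.treatment_effects.items()
        }
    effects: dict[str, dict[str, float]] = {}
    for taxon in taxon_ids:
        if rng.random() < cfg.responsive_fraction:
            shared = rng.normal(0.0, cfg.treatment_effect_sd)
            effects[taxon] = {
                t.value: float(shared + rng.normal(0.0, cfg.treatment_effect_within_sd))
                for t in _GRAZING
            }
    return effects


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[CountTable, CountTable, list[SampleMetadata], SyntheticTruth]:
    """Generate paired fungal/bacterial count tables, metadata and ground truth.

    The latent log-abundance of taxon ``t`` in sample ``s`` is
    ``base_t + treatment_shift + steer_effect + sum_k L_tk f_ks + noise``;
    counts are multinomial draws at a lognormal per-sample depth from the
    per-kingdom softmax of the latent values.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    s_design, s_effects, s_latent, s_counts = root.spawn(4)
    rng_design = np.random.default_rng(s_design)
    rng_eff = np.random.default_rng(s_effects)
    rng_lat = np.random.default_rng(s_latent)
    rng_cnt = np.random.default_rng(s_counts)

    meta = _design(cfg, rng_design)
    n_samples = len(meta)
    steers = sorted({m.steer_id for m in meta})

    f_ids, f_lineages = _fungal_taxonomy(cfg)
    b_ids, b_lineages = _bacterial_taxonomy(cfg)
    all_ids = f_ids + b_ids
    n_taxa = len(all_ids)

    # planted structure: hubs among target-phylum fungi, partners among bacteria
    planted: list[tuple[str, str, int]] = []
    hub_idx = partner_idx = np.empty(0, dtype=int)
    signs = np.empty(0, dtype=int)
    if cfg.coupling_strength > 0 and cfg.n_hubs > 0 and cfg.partners_per_hub > 0:
        hub_idx = rng_eff.choice(cfg.n_fungal_taxa, size=cfg.n_hubs, replace=False)
        partner_pool = rng_eff.choice(
            cfg.n_bacterial_taxa,
            size=cfg.n_hubs * cfg.partners_per_hub,
            replace=False,
        )
        partner_idx = partner_pool.reshape(cfg.n_hubs, cfg.partners_per_hub)
        signs = np.where(
            rng_eff.random((cfg.n_hubs, cfg.partners_per_hub)) < cfg.coupling_sign_mix,
            -1,
            1,
        )
        for h in range(cfg.n_hubs):
            for j in range(cfg.partners_per_hub):
                planted.append(
                    (f_ids[hub_idx[h]], b_ids[partner_idx[h, j]], int(signs[h, j]))
                )

    effects = _draw_treatment_effects(cfg, all_ids, rng_eff)

    # Baseline log-abundances.  Planted taxa are drawn from the typical
    # community range with a narrower spread so the planted structure
    # concerns ordinary detectable members rather than extreme rare or
    # dominant taxa.
    base = rng_eff.normal(0.0, cfg.base_sd, size=n_taxa)
    planted_taxa = {t for e in planted for t in e[:2]}
    for i, taxon in enumerate(all_ids):
        if taxon in planted_taxa:
            base[i] = rng_eff.normal(cfg.planted_base_mean, cfg.planted_base_sd)

    steer_eff = rng_lat.normal(0.0, cfg.steer_sd, size=(len(steers), n_taxa))
    steer_of = {s: i for i, s in enumerate(steers)}

    # Loading matrix: one factor per hub, loading +c on the hub and
    # sign * c on each partner.  The shared hub factor is what makes the
    # hub a hub: with independent per-pair factors the hub-partner
    # correlations would be bounded by 1/sqrt(partners_per_hub) and no
    # pair screen could recover them.  The price is that a hub's partners
    # co-move as a block; after closure this induces genuine indirect
    # associations, a known property of compositional data that the
    # recovery tests measure rather than hide.
    loadings = np.zeros((n_taxa, cfg.n_hubs))
    partner_load = cfg.coupling_strength
    for h in range(len(hub_idx)):
        loadings[hub_idx[h], h] = cfg.coupling_strength
        for j in range(partner_idx.shape[1]):
            loadings[len(f_ids) + partner_idx[h, j], h] = (
                signs[h, j] * partner_load
            )

    factors = rng_lat.normal(0.0, 1.0, size=(max(len(hub_idx), 1), n_samples))
    latent = np.tile(base, (n_samples, 1))
    for s, m in enumerate(meta):
        if m.treatment is not Treatment.BASELINE:
            for i, taxon in enumerate(all_ids):
                shift = effects.get(taxon, {}).get(m.treatment.value)
                if shift:
                    latent[s, i] += shift
        latent[s] += steer_eff[steer_of[m.steer_id]]
    if len(hub_idx):
        latent += factors[: len(hub_idx)].T @ loadings.T
    latent += rng_lat.normal(0.0, cfg.noise_sd, size=latent.shape)

    # structural zeros
    if cfg.dropout_extra > 0:
        drop = rng_lat.random(latent.shape) < cfg.dropout_extra
        latent[drop] = -np.inf

    def _counts(idx: slice, depth_params: tuple[float, float]) -> np.ndarray:
        sub = latent[:, idx]
        out = np.zeros(sub.shape, dtype=np.int64)
        meanlog, sdlog = depth_params
        for s in range(n_samples):
            row = sub[s] - sub[s].max()
            probs = np.exp(row)
            total = probs.sum()
            if total <= 0:  # pathological: everything dropped
                probs = np.ones_like(probs)
                total = probs.sum()
            probs /= total
            depth = int(round(float(rng_cnt.lognormal(meanlog, sdlog))))
            depth = max(depth, 1)
            out[s] = rng_cnt.multinomial(depth, probs)
        return out

    f_counts = _counts(slice(0, len(f_ids)), cfg.depth_fungal)
    b_counts = _counts(slice(len(f_ids), n_taxa), cfg.depth_bacterial)

    sample_ids = [m.sample_id for m in meta]
    fungal = CountTable(sample_ids, f_ids, f_counts, f_lineages)
    bacterial = CountTable(sample_ids, b_ids, b_counts, b_lineages)
    truth = SyntheticTruth(planted_edges=planted, group_effects=effects, seed=cfg.seed)
    return fungal, bacterial, meta, truth


def null_dataset(
    cfg: SyntheticConfig,
) -> tuple[CountTable, CountTable, list[SampleMetadata], SyntheticTruth]:
    """Same generative model with couplings and treatment effects forced to zero.

    Used as the type-I-error harness: downstream network and
    differential-abundance calls on this output should retain ~nothing.
    """
    null_cfg = replace(cfg, coupling_strength=0.0, treatment_effects={},
                       responsive_fraction=0.0)
    fungal, bacterial, meta, truth = generate_dataset(null_cfg)
    assert truth.planted_edges == []
    return fungal, bacterial, meta, truth
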