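"""Synthetic metabolome, mortality, and network generators.

These generators emulate the statistical structure of a two-regime
experimental-evolution metabolomics study: two selection regimes (A =
accelerated, 10-day generation cycle; C = control, 28-day cycle), each with
long-standing and recently derived selection histories, five replicate
populations per regime x history cell, pooled female samples collected at
several ages (days from egg), profiled by LC-MS in a small number of
batches.  The default configuration yields the study shape: 202 metabolites
across 80 pooled samples (2 regimes x 2 histories x 5 replicates x 4 ages),
3 batches.

The generative model works on a latent log scale.  A metabolite's latent
value is a baseline plus, depending on planted effect indicators, a
regime-specific aging slope, a regime offset, an extra regime-specific
interaction slope, and a regime x history offset, plus a replicate random
intercept, a batch effect, and residual noise.  Latents are exponentiated
before emission so the pipeline's log-transform operates on a positive
scale, as LC-MS peak areas do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable, make_metadata

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_metabolome",
    "simulate_mortality",
    "simulate_network",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic metabolome generator.

    All effect magnitudes are on the latent log-abundance scale
    (dimensionless log units); slopes are log units per day.
    """

    n_metabolites: int = 202
    n_replicates_per_population: int = 5
    regimes: tuple[str, ...] = ("A", "C")
    histories: tuple[str, ...] = ("long", "recent")
    ages_by_regime: dict = field(
        default_factory=lambda: {"A": [9, 21, 28, 35], "C": [21, 28, 35, 70]}
    )
    n_batches: int = 3
    # A-type populations age roughly twice as fast as controls by design.
    latent_aging_slope: dict = field(default_factory=lambda: {"A": 0.04, "C": 0.02})
    history_effect_size: float = 0.0
    regime_effect_size: float = 0.5
    interaction_slope: float = 0.02
    eclosion_effect_size: float = 1.0
    batch_sd: float = 0.3
    replicate_sd: float = 0.15
    residual_sd: float = 0.15
    frac_age_responsive: float = 0.4
    frac_regime_responsive: float = 0.3
    frac_interaction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("batch_sd", "replicate_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_age_responsive", "frac_regime_responsive", "frac_interaction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be >= 1")
        if self.n_replicates_per_population < 1:
            raise ValueError("n_replicates_per_population must be >= 1")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        for regime in self.regimes:
            ages = self.ages_by_regime.get(regime, [])
            if len(ages) < 2:
                raise ValueError(
                    f"regime {regime!r} has fewer than 2 sampled ages; "
                    "clock fitting is impossible"
                )
            if any(b <= a for a, b in zip(ages, ages[1:])):
                raise ValueError(f"ages for regime {regime!r} must be strictly increasing")
            if regime not in self.latent_aging_slope:
                raise ValueError(f"latent_aging_slope missing regime {regime!r}")


@dataclass
class GroundTruth:
    """Planted per-metabolite effects behind a simulated metabolome.

    ``effects`` is indexed by metabolite identifier with boolean indicator
    columns (age_responsive, regime_responsive, interaction,
    history_responsive, eclosion_affected) and the signed per-metabolite
    multipliers used for each effect.
    """

    effects: pd.DataFrame
    latent_aging_slope: dict
    pathway_memberships: dict = field(default_factory=dict)


def _pick(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    k = int(round(frac * n))
    if k:
        mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def simulate_metabolome(config: SimulationConfig) -> tuple[AbundanceTable, GroundTruth]:
    """Simulate a raw (positive-scale) abundance table plus its ground truth.

    One row is emitted per (regime, history, replicate, age); the day-9
    accelerated-regime samples additionally receive a post-eclosion offset
    on a random 30% of metabolites, so downstream exclusion logic has a
    physiologically distinct group to exclude.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_metabolites
    metabolites = [f"met_{i + 1:04d}" for i in range(m)]

    baseline = rng.normal(4.0, 1.0, size=m)
    sign = rng.choice([-1.0, 1.0], size=m)
    magnitude = rng.uniform(0.5, 1.5, size=m)

    age_resp = _pick(rng, m, config.frac_age_responsive)
    regime_resp = _pick(rng, m, config.frac_regime_responsive)
    interaction = _pick(rng, m, config.frac_interaction)
    history_resp = _pick(rng, m, 0.5 if config.history_effect_size != 0 else 0.0)
    eclosion = _pick(rng, m, 0.3)

    # centering age keeps latents near baseline so exp() stays well-scaled
    all_ages = sorted({a for ages in config.ages_by_regime.values() for a in ages})
    age_center = float(np.mean(all_ages))

    records = []
    rows = []
    replicate_effects: dict[str, np.ndarray] = {}
    sample_no = 0
    for regime in config.regimes:
        for history in config.histories:
            for rep in range(1, config.n_replicates_per_population + 1):
                rep_id = f"{regime}-{history}-{rep}"
                replicate_effects[rep_id] = rng.normal(0.0, config.replicate_sd, size=m)
                for age in config.ages_by_regime[regime]:
                    sample_no += 1
                    latent = baseline.copy()
                    slope = config.latent_aging_slope[regime]
                    latent += age_resp * sign * magnitude * slope * (age - age_center)
                    if regime == "A":
                        latent += regime_resp * sign * magnitude * config.regime_effect_size
                        latent += (
                            interaction
                            * sign
                            * magnitude
                            * config.interaction_slope
                            * (age - age_center)
                        )
                        if history == "recent":
                            latent += history_resp * sign * config.history_effect_size
                        if age == 9:
                            latent += eclosion * sign * config.eclosion_effect_size
                    elif history == "recent":
                        latent -= history_resp * sign * config.history_effect_size
                    latent += replicate_effects[rep_id]
                    rows.append(latent)
                    records.append(
                        {
                            "sample_id": f"S{sample_no:03d}",
                            "regime": regime,
                            "history": history,
                            "replicate": rep_id,
                            "age_days": age,
                            "n_pooled": 50,
                        }
                    )

    n = len(rows)
    latents = np.asarray(rows)

    # batch assignment: seeded permutation cut into near-equal runs
    order = rng.permutation(n)
    batch_of = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(order, config.n_batches), start=1):
        batch_of[chunk] = b
    batch_effect = rng.normal(0.0, config.batch_sd, size=(config.n_batches, m))
    latents += batch_effect[batch_of - 1]
    latents += rng.normal(0.0, config.residual_sd, size=latents.shape)

    for rec, b in zip(records, batch_of):
        rec["batch"] = int(b)

    meta = make_metadata(records)
    values = pd.DataFrame(np.exp(latents), index=meta.index, columns=metabolites)
    table = AbundanceTable(values=values, metadata=meta, stage="raw")

    effects = pd.DataFrame(
        {
            "age_responsive": age_resp,
            "regime_responsive": regime_resp,
            "interaction": interaction,
            "history_responsive": history_resp,
            "eclosion_affected": eclosion,
            "sign": sign,
            "magnitude": magnitude,
        },
        index=pd.Index(metabolites, name="metabolite"),
    )
    truth = GroundTruth(effects=effects, latent_aging_slope=dict(config.latent_aging_slope))
    return table, truth


def simulate_mortality(
    regime_params: dict,
    cohort_size: int,
    seed: int,
    n_replicates: int = 5,
    n_cohorts: int = 2,
    max_days: int = 5000,
):
    """Simulate per-day cohort death counts under a discrete Gompertz hazard.

    ``regime_params`` maps regime label -> (baseline hazard, hazard growth
    rate per day); the day-``d`` death probability is
    ``min(1, baseline * exp(growth * d))``.  Two cage cohorts are generated
    per replicate population (pooled downstream).  Every fly dies by the end
    of the series.
    """
    from .mortality import DeathCountTable

    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    for regime, (b, g) in regime_params.items():
        if b < 0 or g < 0:
            raise ValueError(f"hazards for regime {regime!r} must be >= 0")
    rng = np.random.default_rng(seed)
    recs = []
    for regime, (b, g) in regime_params.items():
        for rep in range(1, n_replicates + 1):
            population = f"{regime}{rep}"
            for coh in ("alpha", "beta")[:n_cohorts]:
                cohort = f"{population}-{coh}"
                alive = cohort_size
                day = 0
                while alive > 0:
                    day += 1
                    hazard = min(1.0, b * np.exp(g * day))
                    deaths = int(rng.binomial(alive, hazard)) if hazard < 1.0 else alive
                    if day >= max_days:
                        deaths = alive
                    if deaths:
                        recs.append(
                            {
                                "cohort": cohort,
                                "population": population,
                                "day": day,
                                "deaths": deaths,
                            }
                        )
                    alive -= deaths
    return DeathCountTable(pd.DataFrame.from_records(recs))


def simulate_network(
    n_pathways: int,
    metabolites_per_pathway: int,
    n_background: int,
    seed: int,
):
    """Build a connected metabolite/pathway graph with planted memberships.

    Each pathway node is joined to its own dedicated member metabolites;
    background metabolites attach to random existing metabolite nodes, and
    consecutive pathways are bridged by a metabolite-metabolite edge so the
    graph has a single connected component.  Returns the network plus the
    planted pathway -> member-metabolite map for enrichment-recovery tests.
    """
    import networkx as nx

    from .enrichment import MetaboliteNetwork

    if n_pathways < 1 or metabolites_per_pathway < 1 or n_background < 0:
        raise ValueError("n_pathways, metabolites_per_pathway must be >= 1; n_background >= 0")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    memberships: dict[str, set] = {}
    met_no = 0
    for p in range(1, n_pathways + 1):
        pw = f"pw_{p:02d}"
        g.add_node(pw, type="pathway")
        members = set()
        for _ in range(metabolites_per_pathway):
            met_no += 1
            node = f"met_{met_no:04d}"
            g.add_node(node, type="metabolite")
            g.add_edge(pw, node)
            members.add(node)
        memberships[pw] = members
    # bridge consecutive pathways through one member metabolite each
    pws = sorted(memberships)
    for a, b in zip(pws, pws[1:]):
        u = sorted(memberships[a])[int(rng.integers(len(memberships[a])))]
        v = sorted(memberships[b])[int(rng.integers(len(memberships[b])))]
        g.add_edge(u, v)
    for _ in range(n_background):
        met_no += 1
        node = f"met_{met_no:04d}"
        mets = [x for x, d in g.nodes(data=True) if d["type"] == "metabolite"]
        anchor = mets[int(rng.integers(len(mets)))]
        g.add_node(node, type="metabolite")
        g.add_edge(node, anchor)
    return MetaboliteNetwork(g), memberships
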