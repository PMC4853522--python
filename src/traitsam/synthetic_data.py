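"""Synthetic multi-genotype expression data with trait-linked spike-ins.

The generator emulates the study design the pipeline targets: 8 diverse
rice genotypes grown under a control and a salt-stressed condition with 3
replicate seedlings each (48 arrays), ~44K one-color probes (scaled down),
and 14 continuous morpho-physiological traits measured once per genotype.
Expression follows a log-normal intensity model: on the log2 scale a spiked
probe i tied to trait t is

    log2 x_ij = mu_i + beta_i * y_g(j) + eps_ij,   eps_ij ~ N(0, sigma^2)

where y_g is the genotype's min-max-weighted trait value; non-spiked probes
have beta = 0, and under the control condition all betas are 0 by default
(stress-inducible signal only).  Matrices are emitted on the linear scale
so the preprocessing (quantile normalization + log2) is exercised.  A truth
registry records every spiked probe with its trait and sign, enabling
recall/ranking checks downstream; companion generators plant an enriched GO
term among the spiked probes and a hub node in a random interactome.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .enrichment import GoAnnotation
from .io_formats import CONDITIONS, ExpressionMatrix, InteractionEdges, TraitTable

logger = logging.getLogger("traitsam")

#: the eight diverse genotypes of the emulated design
DEFAULT_GENOTYPES = (
    "Pokkali", "PSBRc50", "IR58", "BRRIdhan29",
    "Banikat", "Nipponbare", "O_latifolia", "O_rufipogon",
)

#: fourteen salinity-relevant morpho-physiological traits
DEFAULT_TRAITS = (
    "shoot_Na", "root_Na", "shoot_K", "root_K",
    "shoot_Na_K", "root_Na_K", "shoot_Cl", "root_Cl",
    "biomass", "shoot_length", "root_length",
    "shoot_water_content", "chlorophyll", "survival_score",
)


class SimulationError(ValueError):
    """Raised for configurations the generator cannot honour."""


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the synthetic dataset.

    Spike effects are log2-scale slopes over the [0, 1] weighted trait:
    magnitudes are drawn from a normal truncated below at ``beta_min`` so
    every spike has |beta|/sigma >= 2 at the defaults (a clearly detectable
    but realistic effect).  ``trait_noise_sd`` adds measurement noise to the
    *reported* trait table only (the expression signal uses the true trait),
    mimicking traits and expression assayed at different stress doses; the
    default is 0 because no magnitude for that mismatch is established.
    """

    n_probes: int = 2000
    genotypes: tuple[str, ...] = DEFAULT_GENOTYPES
    conditions: tuple[str, ...] = CONDITIONS
    replicates: int = 3
    traits: tuple[str, ...] = DEFAULT_TRAITS
    spiked_traits: tuple[str, ...] | None = None  # None -> all traits
    spike_fraction: float = 0.002  # per trait and direction
    beta_mean: float = 3.0
    beta_sd: float = 0.6
    beta_min: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    sigma: float = 0.5
    trait_noise_sd: float = 0.0
    spike_control: bool = False
    # GO-annotation generator
    go_n_terms: int = 30
    go_background_rate: float = 0.02
    go_enrichment_ratio: float = 40.0
    go_min_spiked: int = 5
    # interactome generator
    net_n_edges: int | None = None  # None -> 2 * n_probes
    net_hub_degree: int = 20
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_probes < 10:
            raise SimulationError("need at least 10 probes")
        if self.replicates < 2:
            raise SimulationError("need at least 2 replicates")
        if self.sigma <= 0:
            raise SimulationError("replicate noise sigma must be > 0")
        if not 0 <= self.spike_fraction < 0.5:
            raise SimulationError("spike fraction must lie in [0, 0.5)")
        unknown = set(self.spiked_traits or ()) - set(self.traits)
        if unknown:
            raise SimulationError(f"spiked traits not in trait list: {sorted(unknown)}")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise SimulationError(f"unknown conditions {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("genotypes", "conditions", "traits", "spiked_traits"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-component generators derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _probe_ids(n: int, rng: np.random.Generator) -> list[str]:
    numbers = rng.choice(10 ** 7, size=n, replace=False)
    chroms = rng.integers(1, 13, size=n)
    return [f"Os{c:02d}g{v:07d}" for c, v in zip(chroms, numbers)]


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, TraitTable, pd.DataFrame]:
    """Simulate (expression matrix, trait table, truth registry).

    The truth registry has one row per spiked probe with columns
    ``probe_id``, ``trait``, ``direction`` and ``beta`` (signed log2 slope).
    The matrix is linear-scale; the trait table holds the reported (possibly
    noise-perturbed) per-genotype trait values.
    """
    cfg = config
    rng_ids, rng_traits, rng_spikes, rng_expr, rng_noise = _substreams(cfg.seed, 5)

    probe_ids = _probe_ids(cfg.n_probes, rng_ids)
    genotypes = list(cfg.genotypes)
    G = len(genotypes)

    # per-genotype true trait values; redraw any degenerate trait
    true_traits = pd.DataFrame(index=pd.Index(genotypes, name="genotype"),
                               columns=list(cfg.traits), dtype=float)
    for trait in cfg.traits:
        vals = rng_traits.normal(0.0, 1.0, size=G)
        if np.ptp(vals) == 0:
            raise SimulationError(f"degenerate trait draw for {trait!r}")
        true_traits[trait] = vals
    weights = (true_traits - true_traits.min()) / (true_traits.max() - true_traits.min())

    # spike assignment: disjoint probe sets across every (trait, direction)
    spiked_traits = list(cfg.spiked_traits if cfg.spiked_traits is not None
                         else cfg.traits)
    per_cell = int(round(cfg.spike_fraction * cfg.n_probes))
    if cfg.spike_fraction > 0 and per_cell < 1:
        raise SimulationError(
            f"spike fraction {cfg.spike_fraction} x {cfg.n_probes} probes < 1"
        )
    cells = [(t, sign) for t in spiked_traits for sign in (+1, -1)]
    total = per_cell * len(cells) if cfg.spike_fraction > 0 else 0
    if total > cfg.n_probes:
        raise SimulationError("spike sets exceed the number of probes")
    truth_rows = []
    beta = np.zeros(cfg.n_probes)
    spike_trait_idx = np.full(cfg.n_probes, -1)
    if total:
        chosen = rng_spikes.choice(cfg.n_probes, size=total, replace=False)
        tn = stats.truncnorm((cfg.beta_min - cfg.beta_mean) / cfg.beta_sd, np.inf,
                             loc=cfg.beta_mean, scale=cfg.beta_sd)
        magnitudes = tn.rvs(size=total, random_state=rng_spikes)
        for k, (idx, mag) in enumerate(zip(chosen, magnitudes)):
            trait, sign = cells[k // per_cell]
            beta[idx] = sign * mag
            spike_trait_idx[idx] = list(cfg.traits).index(trait)
            truth_rows.append({
                "probe_id": probe_ids[idx], "trait": trait,
                "direction": "positive" if sign > 0 else "negative",
                "beta": float(sign * mag),
            })
    truth = pd.DataFrame(truth_rows,
                         columns=["probe_id", "trait", "direction", "beta"])

    # expression on the log2 scale, then exponentiated to linear intensities
    mu = rng_expr.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_probes)
    sample_rows = []
    columns = []
    for g in genotypes:
        for cond in cfg.conditions:
            for rep in range(1, cfg.replicates + 1):
                sid = f"{g}.{cond}.r{rep}"
                sample_rows.append({"sample_id": sid, "genotype": g,
                                    "condition": cond, "replicate": rep})
                columns.append((g, cond))
    n_samples = len(columns)
    log2x = np.tile(mu[:, None], (1, n_samples))
    w_matrix = weights.to_numpy()  # G x n_traits, true weighted values
    g_index = {g: i for i, g in enumerate(genotypes)}
    for j, (g, cond) in enumerate(columns):
        active = (cond == "stressed") or cfg.spike_control
        if active and total:
            spiked = spike_trait_idx >= 0
            log2x[spiked, j] += beta[spiked] * w_matrix[g_index[g],
                                                        spike_trait_idx[spiked]]
    log2x += rng_expr.normal(0.0, cfg.sigma, size=log2x.shape)

    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    matrix = ExpressionMatrix(np.exp2(log2x), probe_ids, samples, scale="linear")

    reported = true_traits.copy()
    if cfg.trait_noise_sd > 0:
        reported += rng_noise.normal(0.0, cfg.trait_noise_sd, size=reported.shape)
    trait_table = TraitTable(reported, condition="stressed")
    return matrix, trait_table, truth


PLANTED_TERM = "GO:7700001"


def generate_go_annotation(
    probe_ids: list[str], truth: pd.DataFrame, config: SimulationConfig
) -> GoAnnotation:
    """Random GO annotation with one term planted among the spiked probes.

    Every probe is annotated to 1-3 random background terms; the designated
    term ``PLANTED_TERM`` covers non-spiked probes at
    ``go_background_rate`` and spiked probes at ``go_enrichment_ratio``
    times that rate (capped at 1), so a ratio of 1 makes the term
    statistically indistinguishable from background.
    """
    cfg = config
    rng = _substreams(cfg.seed, 7)[5]
    spiked = [p for p in dict.fromkeys(truth["probe_id"]) if p in set(probe_ids)]
    if cfg.spike_fraction > 0 and len(spiked) < cfg.go_min_spiked:
        raise SimulationError(
            f"only {len(spiked)} spiked probes; planted term needs "
            f">= {cfg.go_min_spiked}"
        )
    terms = [f"GO:{7000000 + k:07d}" for k in range(cfg.go_n_terms)]
    namespaces = {t: ("biological_process", "molecular_function",
                      "cellular_component")[k % 3]
                  for k, t in enumerate(terms)}
    namespaces[PLANTED_TERM] = "biological_process"
    labels = {PLANTED_TERM: "planted salt-response term"}

    gene_to_terms: dict[str, set[str]] = {}
    spiked_set = set(spiked)
    p_spiked = min(1.0, cfg.go_enrichment_ratio * cfg.go_background_rate)
    for p in probe_ids:
        k = int(rng.integers(1, 4))
        assigned = set(rng.choice(terms, size=k, replace=False).tolist())
        rate = p_spiked if p in spiked_set else cfg.go_background_rate
        if rng.random() < rate:
            assigned.add(PLANTED_TERM)
        gene_to_terms[p] = assigned
    return GoAnnotation({g: frozenset(t) for g, t in gene_to_terms.items()},
                        namespaces, labels, set(probe_ids))


def generate_interactome(
    probe_ids: list[str],
    config: SimulationConfig,
    hub: str | None = None,
) -> tuple[InteractionEdges, str]:
    """Random simple interactome with a planted hub node.

    The hub (default: the first probe id; pass a spiked probe to plant it in
    the signal) receives exactly ``net_hub_degree`` edges; the remaining
    edges are sampled uniformly among the other nodes, so the hub's degree
    is exact by construction.  Returns (edges, hub id).
    """
    cfg = config
    if len(probe_ids) < 2:
        raise SimulationError("need at least 2 nodes")
    rng = _substreams(cfg.seed, 7)[6]
    n_edges = cfg.net_n_edges if cfg.net_n_edges is not None else 2 * len(probe_ids)
    if n_edges == 0:
        return InteractionEdges([], namespace="RAP"), hub or probe_ids[0]
    hub = hub if hub is not None else probe_ids[0]
    if hub not in probe_ids:
        raise SimulationError(f"hub {hub!r} not among the nodes")
    others = [p for p in probe_ids if p != hub]
    k = len(others)
    hub_degree = min(cfg.net_hub_degree, k, n_edges)
    max_edges = hub_degree + k * (k - 1) // 2
    if n_edges > max_edges:
        raise SimulationError(
            f"{n_edges} edges exceed the simple-graph maximum {max_edges}"
        )
    neighbours = rng.choice(k, size=hub_degree, replace=False)
    edges = {tuple(sorted((hub, others[i]))) for i in neighbours}
    target = n_edges - hub_degree
    rest: set[tuple[str, str]] = set()
    while len(rest) < target:
        batch = rng.integers(0, k, size=(max(64, 2 * (target - len(rest))), 2))
        for a, b in batch:
            if a == b:
                continue
            e = tuple(sorted((others[a], others[b])))
            rest.add(e)
            if len(rest) >= target:
                break
    edges |= rest
    return InteractionEdges(sorted(edges), namespace="RAP"), hub
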