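"""Synthetic weighted networks and RNA-seq-like counts for the three
simulation scenarios.

The generator emulates a Gaussian-graphical-model RNA-seq simulator: a
degree-heterogeneous random graph is drawn, hub nodes are perturbed to encode
group and/or age effects, edges receive random partial correlations (giving a
positive-definite precision matrix per group x age-category cell), Gaussian
samples are drawn from each cell's graphical model, and each gene column is
mapped through the standard normal CDF followed by the inverse empirical CDF
of a per-gene reference count distribution, yielding integer counts whose
marginals match the reference.

Scenarios
---------
I   — group effect only: group 2 loses all edges of the top
      round(effect_size * p) hubs; the three age-category networks within a
      group are identical.
II  — group and age effects: on top of scenario I, each successive age
      category cumulatively removes all edges of one additional next-ranked
      hub (per group).
III — age as a confounder: both groups share a nested network sequence
      (category 2 = base minus the top-2 hubs' edges, category 3 = category 2
      minus the next-2), but the groups sample age categories with different
      proportions (default 10/10/80 vs 80/10/10), so group differences in
      connectivity are explained entirely by age.

Ages are N(55, 10) with categories cut at 50 and 60. The per-gene reference
count distributions are synthetic negative binomials (log-normal means,
gamma-distributed dispersions); they stand in for an external RNA-seq
reference dataset and are frozen by their own seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "ScenarioConfig",
    "WeightedNetworkSet",
    "SimulatedDataset",
    "ReferenceDistribution",
    "synthetic_reference_distribution",
    "generate_base_network",
    "perturb_for_group",
    "perturb_for_age",
    "assign_partial_correlations",
    "build_networks",
    "sample_expression",
    "simulate_dataset",
]

AGE_CATEGORIES = (1, 2, 3)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-design parameters for one simulation cell."""

    p: int = 20
    n: int = 40
    scenario: str = "I"
    effect_size: float = 0.10
    seed: int = 0
    age_mean: float = 55.0
    age_sd: float = 10.0
    age_cuts: tuple[float, float] = (50.0, 60.0)
    scenario3_props: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.1, 0.1, 0.8),
        (0.8, 0.1, 0.1),
    )
    pcor_range: tuple[float, float] = (0.3, 0.9)
    precision_margin: float = 0.02  # smallest eigenvalue of each precision matrix
    attachment_edges: int = 2  # preferential-attachment edges per new node
    n_ref: int = 2000

    def __post_init__(self) -> None:
        if self.scenario not in {"I", "II", "III"}:
            raise ValueError("scenario must be one of 'I', 'II', 'III'")
        for props in self.scenario3_props:
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError("scenario III proportions must sum to 1 per group")


@dataclass
class WeightedNetworkSet:
    """Adjacency and partial-correlation matrices per (group, age category)."""

    omega: dict          # (z, c) -> {0,1}^{p x p}
    pcor: dict           # (z, c) -> partial correlations
    precision: dict      # (z, c) -> SPD precision matrix
    hub_indices: np.ndarray  # nodes ordered by decreasing base-network degree


@dataclass
class SimulatedDataset:
    expr: ExpressionMatrix
    z: np.ndarray        # group labels in {1, 2}
    age: np.ndarray
    age_category: np.ndarray
    networks: WeightedNetworkSet
    config: ScenarioConfig = field(repr=False, default=None)


class ReferenceDistribution:
    """Per-gene empirical count distribution with inverse-CDF lookup."""

    def __init__(self, samples: np.ndarray):
        samples = np.asarray(samples)
        if samples.ndim != 2:
            raise ValueError("reference samples must be genes x n_ref")
        self._sorted = np.sort(samples, axis=1)

    @property
    def n_genes(self) -> int:
        return self._sorted.shape[0]

    @property
    def n_ref(self) -> int:
        return self._sorted.shape[1]

    def quantile(self, u, gene=None) -> np.ndarray:
        """Inverse empirical CDF: order statistic at ceil(u * n_ref)."""
        u = np.asarray(u, dtype=float)
        idx = np.clip(np.ceil(u * self.n_ref).astype(int) - 1, 0, self.n_ref - 1)
        if gene is not None:
            return self._sorted[gene, idx]
        if u.ndim != 2 or u.shape[1] != self.n_genes:
            raise ValueError("expected an n x p array of uniforms")
        return np.take_along_axis(self._sorted.T, idx, axis=0)


def synthetic_reference_distribution(
    p: int,
    seed,
    n_ref: int = 2000,
    mean_log_mean: float = np.log(100.0),
    mean_log_sd: float = 1.0,
    dispersion_shape: float = 2.0,
    dispersion_scale: float = 2.5,
) -> ReferenceDistribution:
    """Synthetic negative-binomial reference counts, one distribution per gene.

    Gene means are log-normal, dispersions (NB size parameters) gamma. This
    plays the role of an external reference expression dataset for the
    inverse-CDF count mapping without requiring any download.
    """
    if n_ref < 100:
        raise ValueError("n_ref must be at least 100")
    rng = np.random.default_rng(seed)
    means = rng.lognormal(mean_log_mean, mean_log_sd, size=p)
    sizes = rng.gamma(dispersion_shape, dispersion_scale, size=p)
    return reference_from_negative_binomial(means, sizes, n_ref, rng)


def reference_from_negative_binomial(means, sizes, n_ref, seed) -> ReferenceDistribution:
    """Reference built from explicit NB(mean, size) parameters per gene."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.atleast_1d(np.asarray(means, dtype=float))
    sizes = np.atleast_1d(np.asarray(sizes, dtype=float))
    prob = sizes / (sizes + means)
    samples = rng.negative_binomial(sizes[:, None], prob[:, None], size=(means.size, n_ref))
    return ReferenceDistribution(samples)


def generate_base_network(p: int, seed, attachment_edges: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Connected degree-heterogeneous random graph and its hub ranking.

    A preferential-attachment graph guarantees well-separated hubs ("nodes
    with the most number of edges"). Returns the adjacency matrix and node
    indices ordered by decreasing degree (ties broken by index).
    """
    if p < 5:
        raise ValueError("need at least 5 genes for a hub-containing network")
    rng = np.random.default_rng(seed)
    graph_seed = int(rng.integers(2**31 - 1))
    g = nx.barabasi_albert_graph(p, m=min(attachment_edges, p - 1), seed=graph_seed)
    adj = nx.to_numpy_array(g, nodelist=range(p))
    degrees = adj.sum(axis=0)
    hub_ranking = np.argsort(-degrees, kind="stable")
    return adj.astype(int), hub_ranking


def _remove_hub_edges(adj: np.ndarray, hubs) -> np.ndarray:
    out = adj.copy()
    hubs = np.atleast_1d(hubs)
    out[hubs, :] = 0
    out[:, hubs] = 0
    return out


def perturb_for_group(adj: np.ndarray, hub_ranking, effect_size: float) -> np.ndarray:
    """Group-2 network: the top round(effect_size * p) hubs lose all edges."""
    p = adj.shape[0]
    n_hubs = int(round(effect_size * p))
    if n_hubs < 1:
        raise ValueError("effect_size * p must be at least 1")
    return _remove_hub_edges(adj, np.asarray(hub_ranking)[:n_hubs])


def perturb_for_age(
    adj: np.ndarray, hub_ranking, scenario: str, effect_size: float = 0.10
) -> dict:
    """Per-(group, age category) adjacency matrices for one scenario."""
    hub_ranking = np.asarray(hub_ranking)
    p = adj.shape[0]
    omega: dict = {}
    if scenario in {"I", "II"}:
        n_group_hubs = int(round(effect_size * p))
        # effect_size 0 is the null configuration: both groups keep the base
        # network, which calibrates the false-flag rate with no true DC gene
        group2 = adj if n_group_hubs == 0 else perturb_for_group(adj, hub_ranking, effect_size)
        base = {1: adj, 2: group2}
        for z in (1, 2):
            current = base[z]
            for c in AGE_CATEGORIES:
                if scenario == "II" and c > 1:
                    extra_idx = n_group_hubs + (c - 2)
                    if extra_idx >= p:
                        raise ValueError("more hub removals requested than nodes")
                    current = _remove_hub_edges(current, hub_ranking[extra_idx])
                omega[(z, c)] = current
    else:  # scenario III: groups share one nested sequence across categories
        if p < 4:
            raise ValueError("more hub removals requested than nodes")
        second = _remove_hub_edges(adj, hub_ranking[:2])
        third = _remove_hub_edges(second, hub_ranking[2:4])
        seq = {1: adj, 2: second, 3: third}
        for z in (1, 2):
            for c in AGE_CATEGORIES:
                omega[(z, c)] = seq[c]
    return omega


def assign_partial_correlations(
    adj: np.ndarray,
    seed,
    magnitude_range: tuple[float, float] = (0.3, 0.9),
    weights: np.ndarray | None = None,
    diagonal: float | None = None,
    margin: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Weight an adjacency into an SPD precision matrix and partial correlations.

    Off-diagonal precision entries are drawn uniform in ``magnitude_range``
    with random sign (or taken from ``weights`` so that nested networks share
    edge weights); the constant diagonal is inflated just past the most
    negative eigenvalue of the off-diagonal part, so every generated
    precision matrix is positive definite with smallest eigenvalue
    ``margin`` (and an empty adjacency yields the identity). Partial
    correlations follow as -omega_jk / sqrt(omega_jj * omega_kk), so their
    support equals the adjacency support exactly.
    """
    adj = np.asarray(adj)
    p = adj.shape[0]
    if weights is None:
        weights = draw_edge_weights(p, seed, magnitude_range)
    prec = weights * (adj > 0)
    prec = np.triu(prec, 1) + np.triu(prec, 1).T
    if diagonal is None:
        lam_min = np.linalg.eigvalsh(prec).min() if adj.any() else 0.0
        diagonal = max(1.0, margin - lam_min)
    np.fill_diagonal(prec, diagonal)
    pcor = -prec / diagonal
    np.fill_diagonal(pcor, 0.0)
    pcor[adj == 0] = 0.0
    return prec, pcor


def draw_edge_weights(p: int, seed, magnitude_range=(0.3, 0.9)) -> np.ndarray:
    """Symmetric matrix of signed edge weights for every potential edge."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = magnitude_range
    mag = rng.uniform(lo, hi, size=(p, p))
    sign = rng.choice([-1.0, 1.0], size=(p, p))
    w = mag * sign
    w = np.triu(w, 1)
    return w + w.T


def build_networks(config: ScenarioConfig, seed) -> WeightedNetworkSet:
    """Fresh ground-truth weighted networks for one replicate.

    All (z, c) cells derive from one base graph and one shared edge-weight
    draw, so edges surviving a perturbation keep their weights across cells.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    adj, hubs = generate_base_network(config.p, rng, config.attachment_edges)
    omega = perturb_for_age(adj, hubs, config.scenario, config.effect_size)
    weights = draw_edge_weights(config.p, rng, config.pcor_range)
    # one diagonal fixed by the unperturbed network: removing a hub's edges
    # then leaves every surviving edge's partial correlation unchanged, and
    # eigenvalue interlacing keeps all perturbed matrices positive definite
    base_off = weights * (adj > 0)
    lam_min = np.linalg.eigvalsh(base_off).min()
    diagonal = max(1.0, config.precision_margin - lam_min)
    precision, pcor = {}, {}
    cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}
    for key, a in omega.items():
        token = a.tobytes()
        if token not in cache:
            cache[token] = assign_partial_correlations(
                a, rng, config.pcor_range, weights=weights, diagonal=diagonal
            )
        precision[key], pcor[key] = cache[token]
    return WeightedNetworkSet(omega=omega, pcor=pcor, precision=precision, hub_indices=hubs)


def _age_category(age: np.ndarray, cuts: tuple[float, float]) -> np.ndarray:
    return 1 + (age >= cuts[0]).astype(int) + (age > cuts[1]).astype(int)


def _truncnorm_in_category(c: int, config: ScenarioConfig, rng, size: int) -> np.ndarray:
    lo_cut, hi_cut = config.age_cuts
    bounds = {1: (-np.inf, lo_cut), 2: (lo_cut, hi_cut), 3: (hi_cut, np.inf)}[c]
    a = (bounds[0] - config.age_mean) / config.age_sd
    b = (bounds[1] - config.age_mean) / config.age_sd
    return stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=size, random_state=rng
    )


def sample_expression(
    networks: WeightedNetworkSet,
    config: ScenarioConfig,
    seed,
    reference: ReferenceDistribution | None = None,
) -> SimulatedDataset:
    """Draw ages, groups and counts from a weighted network set.

    Each sample's Gaussian expression vector is drawn from the multivariate
    normal implied by its (group, age category) precision matrix, then mapped
    gene-wise through Phi and the reference inverse empirical CDF to counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if reference is None:
        reference = synthetic_reference_distribution(config.p, rng, config.n_ref)
    n = config.n
    if n < 8:
        raise ValueError("n too small to split into two groups of >= 4")
    n1 = n // 2
    z = np.repeat([1, 2], [n1, n - n1])

    age = np.empty(n)
    if config.scenario == "III":
        category = np.empty(n, dtype=int)
        for gi, lab in enumerate((1, 2)):
            idx = np.flatnonzero(z == lab)
            props = np.asarray(config.scenario3_props[gi])
            category[idx] = rng.choice(AGE_CATEGORIES, size=idx.size, p=props)
        for c in AGE_CATEGORIES:
            mask = category == c
            if mask.any():
                age[mask] = _truncnorm_in_category(c, config, rng, int(mask.sum()))
    else:
        age = rng.normal(config.age_mean, config.age_sd, size=n)
        category = _age_category(age, config.age_cuts)

    # standardize each gene's marginal to N(0, 1) before the probability
    # integral transform, so the inverse-CDF mapping preserves the reference
    # marginals exactly
    factors = {}
    for key, prec in networks.precision.items():
        cov = np.linalg.inv(prec)
        factors[key] = np.linalg.cholesky(cov) / np.sqrt(np.diag(cov))[:, None]
    gauss = np.empty((n, config.p))
    for key, l in factors.items():
        mask = (z == key[0]) & (category == key[1])
        if mask.any():
            gauss[mask] = rng.standard_normal((int(mask.sum()), config.p)) @ l.T

    counts = reference.quantile(stats.norm.cdf(gauss))
    expr = ExpressionMatrix(
        counts.astype(float),
        [f"S{i + 1}" for i in range(n)],
        [f"G{j + 1}" for j in range(config.p)],
    )
    return SimulatedDataset(
        expr=expr, z=z, age=age, age_category=category, networks=networks, config=config
    )


def simulate_dataset(
    config: ScenarioConfig, reference: ReferenceDistribution | None = None
) -> SimulatedDataset:
    """Networks + expression for one replicate, reproducible from config.seed."""
    rng = np.random.default_rng(config.seed)
    networks = build_networks(config, rng)
    return sample_expression(networks, config, rng, reference)
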