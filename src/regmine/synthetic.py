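"""Ground-truth generators: linear-ODE networks, lagged pairs, toy GO DAGs.

The expression simulator draws a sparse signed network and integrates
linear dynamics dx/dt = M x (+ perturbation) with white process noise, in
three sampling regimes: a dynamic time series after an initial
perturbation, global steady states with all genes perturbed per sample,
and local steady states with one gene perturbed per experiment. Network
edges become gold-standard positive pairs, sampled non-edges the
negatives, so the whole pipeline can be trained and scored without any
external data.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .features import feature_frame
from .io import DataError, ExpressionMatrix, GenePair, GOAnnotationSet

SIM_MODES = ("dynamic", "global", "local")

#: divergence guard for the Euler integration
_STATE_LIMIT = 1e6


@dataclass
class SyntheticNetwork:
    """A sparse signed regulator -> target weight matrix with self-decay.

    ``adjacency[r, t]`` is the weight of regulator r on target t (0 = no
    edge); ``self_decay`` holds the strictly negative diagonal terms. The
    ODE system matrix is M = adjacency.T + diag(self_decay).
    """

    gene_ids: list[str]
    adjacency: np.ndarray
    self_decay: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        self.adjacency = np.asarray(self.adjacency, float)
        self.self_decay = np.asarray(self.self_decay, float)
        if self.adjacency.shape != (n, n) or self.self_decay.shape != (n,):
            raise ValueError("inconsistent network dimensions")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("regulatory adjacency must have a zero diagonal")
        if np.any(self.self_decay >= 0):
            raise ValueError("self-decay terms must be strictly negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def ode_matrix(self) -> np.ndarray:
        return self.adjacency.T + np.diag(self.self_decay)

    def edges(self) -> list[tuple[str, str]]:
        """Directed regulator -> target edges (the gold-standard positives)."""
        rr, tt = np.nonzero(self.adjacency)
        return [(self.gene_ids[r], self.gene_ids[t]) for r, t in zip(rr, tt)]

    def non_edges(self) -> list[tuple[str, str]]:
        """All ordered gene pairs (r != t) without a regulatory edge."""
        out = []
        for r in range(self.n_genes):
            for t in range(self.n_genes):
                if r != t and self.adjacency[r, t] == 0:
                    out.append((self.gene_ids[r], self.gene_ids[t]))
        return out


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling regime and noise settings for one simulated experiment.

    In dynamic mode the series is a concatenation of perturbation
    episodes: every ``episode_length`` samples the state is re-displaced
    (uniform +/- perturb_magnitude), so the recorded samples keep tracking
    informative relaxation transients instead of decaying to pure noise.
    ``episode_length`` = n_samples reduces to a single perturbed initial
    state.
    """

    mode: str = "dynamic"
    n_samples: int = 100
    noise_sd: float = 0.1
    dt: float = 0.1
    perturb_magnitude: float = 1.0
    seed: int = 0
    burn_in: int = 5
    episode_length: int = 10
    init_state: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mode not in SIM_MODES:
            raise ValueError(f"mode must be one of {SIM_MODES}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_samples < 1 or self.dt <= 0:
            raise ValueError("n_samples must be >= 1 and dt > 0")


def make_network(n_genes: int, density: float, seed: int) -> SyntheticNetwork:
    """Random sparse network: edge weights uniform in +/-[0.5, 1.5] at the
    given density, self-decay uniform in [-1.5, -0.5]."""
    if not 0 < density <= 0.5:
        raise ValueError("density must be in (0, 0.5]")
    if n_genes < 3:
        raise ValueError("need at least 3 genes")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    mask = rng.random((n_genes, n_genes)) < density
    np.fill_diagonal(mask, False)
    magnitude = rng.uniform(0.5, 1.5, size=(n_genes, n_genes))
    sign = rng.choice([-1.0, 1.0], size=(n_genes, n_genes))
    adjacency = np.where(mask, magnitude * sign, 0.0)
    self_decay = rng.uniform(-1.5, -0.5, size=n_genes)
    return SyntheticNetwork(gene_ids, adjacency, self_decay)


def _gold_pairs(
    network: SyntheticNetwork, rng: np.random.Generator
) -> list[GenePair]:
    positives = [GenePair(r, t, "positive") for r, t in network.edges()]
    non_edges = network.non_edges()
    n_neg = min(len(positives), len(non_edges))
    chosen = rng.choice(len(non_edges), size=n_neg, replace=False)
    negatives = [
        GenePair(non_edges[i][0], non_edges[i][1], "negative")
        for i in sorted(int(c) for c in chosen)
    ]
    return positives + negatives


def simulate(
    network: SyntheticNetwork, config: SimulationConfig
) -> tuple[ExpressionMatrix, list[GenePair]]:
    """Simulate expression data plus gold-standard labeled pairs.

    dynamic: Euler integration of dx/dt = M x across perturbation
    episodes (the state is re-displaced every ``episode_length`` samples),
    recording ``n_samples`` consecutive points after a short burn-in.
    global: ``n_samples`` independent steady states, all genes perturbed.
    local: one steady-state experiment per single-gene perturbation.
    Every recorded value carries additive white measurement noise
    N(0, noise_sd). Any state exceeding 1e6 aborts with advice to reduce
    dt.
    """
    rng = np.random.default_rng(config.seed)
    m = network.ode_matrix()
    n = network.n_genes
    pm = config.perturb_magnitude

    if config.mode == "dynamic":
        if config.init_state is not None:
            x = np.asarray(config.init_state, float).copy()
            if x.shape != (n,):
                raise ValueError("init_state has wrong length")
        else:
            x = rng.uniform(-pm, pm, size=n)
        samples = np.empty((config.n_samples, n))
        for step in range(config.burn_in + config.n_samples):
            recorded = step - config.burn_in
            if recorded > 0 and recorded % config.episode_length == 0:
                x = rng.uniform(-pm, pm, size=n)
            x = x + config.dt * (m @ x)
            if np.max(np.abs(x)) > _STATE_LIMIT:
                raise DataError(
                    "integration diverged (|x| > 1e6); use a smaller dt"
                )
            if recorded >= 0:
                samples[recorded] = x
        labels = [f"t{i}" for i in range(config.n_samples)]
        values = samples.T
        is_timeseries = True
    elif config.mode == "global":
        values = np.empty((n, config.n_samples))
        for j in range(config.n_samples):
            p = rng.uniform(-pm, pm, size=n)
            values[:, j] = _steady_state(m, p)
        labels = [f"s{j}" for j in range(config.n_samples)]
        is_timeseries = False
    else:  # local
        values = np.empty((n, n))
        for j in range(n):
            p = np.zeros(n)
            p[j] = pm
            values[:, j] = _steady_state(m, p)
        labels = [f"perturb_{g}" for g in network.gene_ids]
        is_timeseries = False

    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    matrix = ExpressionMatrix(
        gene_ids=list(network.gene_ids),
        measurement_labels=labels,
        values=values,
        is_timeseries=is_timeseries,
    )
    return matrix, _gold_pairs(network, rng)


def _steady_state(m: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Solve M x + p = 0."""
    try:
        x = np.linalg.solve(m, -p)
    except np.linalg.LinAlgError as exc:
        raise DataError(f"singular system matrix: {exc}") from exc
    if np.max(np.abs(x)) > _STATE_LIMIT:
        raise DataError("steady state exceeds 1e6; network nearly singular")
    return x


def make_lagged_pairs(
    n_pairs: int,
    lag_set: Sequence[int] = (1, 2, 3),
    noise_sd: float = 0.1,
    length: int = 18,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[tuple[GenePair, int]]]:
    """Pairs where the target is a lagged, noisy copy of the TF profile.

    Each TF profile is an induction/repression pulse pair — one positive
    and one negative Gaussian bump at random well-separated interior
    positions, over a small band-limited noise background, standardized
    to sd 1. The bump centers are placed so that both extrema stay in the
    interior of the series for the TF and for its lag-shifted copy. TG
    equals TF shifted right by its lag plus N(0, noise_sd). Lags cycle
    deterministically through ``lag_set``. Returns the expression matrix
    and (pair, true_lag) records; the true direction of every pair is
    forward (TF -> TG).
    """
    lag_set = [int(l) for l in lag_set]
    if any(l < 0 or l >= length / 2 for l in lag_set):
        raise ValueError("lags must satisfy 0 <= lag < length/2")
    rng = np.random.default_rng(seed)
    max_lag = max(lag_set)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    out_pairs: list[tuple[GenePair, int]] = []
    width = len(str(max(n_pairs, 1)))
    latent_len = length + max_lag
    t_lat = np.arange(latent_len, dtype=float)
    sep = 6  # min distance between the two pulse centers
    # centers must stay interior to the TF window (starts at max_lag) and
    # to every lag-shifted window (the earliest starts at 0, length long)
    lo, hi = max_lag + 2.0, float(length - 3)
    for i in range(n_pairs):
        lag = lag_set[i % len(lag_set)]
        c1 = rng.uniform(lo, hi - sep)
        c2 = rng.uniform(c1 + sep, hi)
        amp1, amp2 = rng.uniform(0.8, 1.3, size=2)
        sig1, sig2 = rng.uniform(1.0, 1.5, size=2)
        flip = 1.0 if rng.random() < 0.5 else -1.0
        curve = flip * (
            amp1 * np.exp(-0.5 * ((t_lat - c1) / sig1) ** 2)
            - amp2 * np.exp(-0.5 * ((t_lat - c2) / sig2) ** 2)
        )
        background = 0.15 * gaussian_filter1d(
            rng.standard_normal(latent_len), sigma=2.0, mode="nearest"
        )
        smooth = curve + background
        smooth = (smooth - smooth.mean()) / max(smooth.std(), 1e-12)
        tf = smooth[max_lag:]
        tg = smooth[max_lag - lag : max_lag - lag + length].copy()
        if noise_sd > 0:
            tg = tg + rng.normal(0.0, noise_sd, size=length)
        tf_id = f"TF{i:0{width}d}"
        tg_id = f"TG{i:0{width}d}"
        gene_ids.extend([tf_id, tg_id])
        rows.extend([tf, tg])
        out_pairs.append((GenePair(tf_id, tg_id, "positive"), lag))
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        measurement_labels=[f"t{t}" for t in range(length)],
        values=np.vstack(rows),
        is_timeseries=True,
    )
    return matrix, out_pairs


def _random_term_dag(
    n_terms: int, depth: int, rng: np.random.Generator
) -> tuple[dict[str, set[str]], list[str]]:
    """A rooted random tree over n_terms terms reaching the requested depth.

    Returns (child -> parents map, terms ordered by grade).
    """
    terms = [f"T{i:03d}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {terms[0]: set()}
    grade = {terms[0]: 1}
    # a guaranteed chain down to `depth`
    for i in range(1, min(depth, n_terms)):
        parents[terms[i]] = {terms[i - 1]}
        grade[terms[i]] = i + 1
    for i in range(min(depth, n_terms), n_terms):
        parent = terms[int(rng.integers(0, i))]
        parents[terms[i]] = {parent}
        grade[terms[i]] = grade[parent] + 1
    ordered = sorted(terms, key=lambda t: grade[t])
    return parents, ordered


def make_toy_go(
    n_terms: int = 80,
    depth: int = 7,
    n_genes: int = 60,
    coann_bias: float = 0.6,
    seed: int = 0,
) -> tuple[GOAnnotationSet, list[GenePair]]:
    """A toy GO DAG with gene annotations and labeled gene pairs.

    Every gene receives two random term annotations. Positive pairs are
    additionally co-annotated to one common deep term with probability
    ``coann_bias``; negative pairs stay independent, so the bias knob
    controls how separable the GO score is between the two classes.
    """
    if depth < 3:
        raise ValueError("depth must be >= 3")
    rng = np.random.default_rng(seed)
    parents, ordered = _random_term_dag(n_terms, depth, rng)
    deep_terms = ordered[-max(1, n_terms // 3):]
    genes = [f"g{i:03d}" for i in range(n_genes)]
    gene_terms: dict[str, set[str]] = {
        g: {ordered[int(k)] for k in rng.integers(0, n_terms, size=2)}
        for g in genes
    }
    pairs: list[GenePair] = []
    order = rng.permutation(n_genes)
    n_slots = n_genes // 2
    for slot in range(n_slots):
        a, b = genes[order[2 * slot]], genes[order[2 * slot + 1]]
        if slot < n_slots // 2:
            if rng.random() < coann_bias:
                shared = deep_terms[int(rng.integers(0, len(deep_terms)))]
                gene_terms[a].add(shared)
                gene_terms[b].add(shared)
            pairs.append(GenePair(a, b, "positive"))
        else:
            pairs.append(GenePair(a, b, "negative"))
    go = GOAnnotationSet.build(parents, gene_terms)
    return go, pairs


def annotate_network_go(
    network: SyntheticNetwork,
    coann_bias: float = 0.6,
    n_terms: int = 80,
    depth: int = 7,
    seed: int = 0,
) -> GOAnnotationSet:
    """Toy GO annotations for a network's genes, biased along true edges.

    Each gene gets two random terms. Each regulator -> target edge is,
    with probability ``coann_bias``, co-annotated to its own specific
    process term — a fresh leaf hung under a random deep term — emulating
    regulon-specific annotation: the two genes of a co-regulated pair
    share a deep specific term, while unrelated genes share at most
    shallow ancestors.
    """
    rng = np.random.default_rng(seed)
    parents, ordered = _random_term_dag(n_terms, depth, rng)
    deep_terms = ordered[-max(1, n_terms // 3):]
    gene_terms: dict[str, set[str]] = {
        g: {ordered[int(k)] for k in rng.integers(0, n_terms, size=2)}
        for g in network.gene_ids
    }
    for k, (r, t) in enumerate(network.edges()):
        if rng.random() < coann_bias:
            anchor = deep_terms[int(rng.integers(0, len(deep_terms)))]
            specific = f"T_edge{k:03d}"
            parents[specific] = {anchor}
            gene_terms[r].add(specific)
            gene_terms[t].add(specific)
    return GOAnnotationSet.build(parents, gene_terms)


def benchmark_dataset(
    n_pos: int = 300,
    n_neg: int = 300,
    n_genes: int = 10,
    density: float = 0.2,
    mode: str = "dynamic",
    n_samples: int = 100,
    noise_sd: float = 0.1,
    coann_bias: float = 0.6,
    seed: int = 42,
    max_networks: int = 400,
) -> pd.DataFrame:
    """The standard labeled benchmark: features pooled over many networks.

    A single small network yields at most n_genes*(n_genes-1) pairs, so the
    benchmark accumulates gold pairs and their features over independently
    seeded networks (each with its own simulation and toy GO annotation)
    until the requested counts are reached. Networks whose random weights
    make the integration diverge are skipped and redrawn.
    """
    rng = np.random.default_rng(seed)
    frames: list[pd.DataFrame] = []
    got_pos = got_neg = 0
    for _ in range(max_networks):
        if got_pos >= n_pos and got_neg >= n_neg:
            break
        sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]
        network = make_network(n_genes, density, seed=sub[0])
        if not network.edges():
            continue
        config = SimulationConfig(
            mode=mode, n_samples=n_samples, noise_sd=noise_sd, seed=sub[1]
        )
        try:
            matrix, gold = simulate(network, config)
        except DataError:
            continue  # unstable draw; the seeded sequence moves on
        go = annotate_network_go(network, coann_bias=coann_bias, seed=sub[2])
        frame = feature_frame(matrix, gold, go)
        frames.append(frame)
        got_pos += int((frame["label"] == 1.0).sum())
        got_neg += int((frame["label"] == 0.0).sum())
    if got_pos < n_pos or got_neg < n_neg:
        raise DataError(
            f"could not accumulate {n_pos}/{n_neg} pairs in {max_networks} networks"
        )
    pooled = pd.concat(frames, ignore_index=True)
    pos_rows = pooled[pooled["label"] == 1.0].head(n_pos)
    neg_rows = pooled[pooled["label"] == 0.0].head(n_neg)
    return pd.concat([pos_rows, neg_rows], ignore_index=True)
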