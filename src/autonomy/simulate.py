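"""Synthetic data with the statistical structure the pipeline assumes.

Three generators, all seeded and byte-deterministic:

* ``simulate_expression`` — a two-condition log2 expression matrix with a
  planted up/down signature (default 29 up / 3 down genes, 2.0 log2-unit
  effect) on top of background genes, a fraction of which are bimodal
  high/low independent of condition (the step structure StepMiner expects).
* ``simulate_survival`` — exponential event times whose hazard scales as
  exp(beta * standardised score), with independent exponential censoring.
* ``simulate_graph`` — an Erdős–Rényi background with planted high-degree
  hub nodes.

The Gaussian log-scale model is deliberate: every downstream stage
(step fitting, modified Z-scores, Welch tests) operates on log values, so
the generator targets that level directly. ``simulate_counts`` provides a
Poisson count mode for exercising the log-CPM I/O path only.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSignature


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort, signature, survival and graph.

    Expression: ``n_genes`` total genes, ``n_per_group`` samples in each of
    two conditions; the first ``n_up`` + ``n_down`` genes carry a planted
    log2 shift of ``effect`` (up in group A, resp. down) around the midpoint
    of the two background mode centres; ``bimodal_frac`` of background genes
    are split between the low/high centres (2.0 / 6.0 by default)
    independently of condition; Gaussian noise sd ``noise_sd``.

    Survival: event hazard ``baseline_hazard`` * exp(beta * z-scored score),
    exponential censoring at rate ``censor_rate``.

    Graph: ER background G(n_background, edge_prob) plus ``n_hubs`` planted
    nodes each wired to ``hub_degree`` random other nodes.
    """

    n_genes: int = 500
    n_per_group: int = 20
    n_up: int = 29
    n_down: int = 3
    effect: float = 2.0
    noise_sd: float = 0.5
    bimodal_frac: float = 0.3
    baseline_low: float = 2.0
    baseline_high: float = 6.0
    seed: int = 0
    group_labels: tuple[str, str] = ("autonomous", "control")
    baseline_hazard: float = 0.1
    beta: float = 1.5
    censor_rate: float = 0.02
    n_background: int = 200
    edge_prob: float = 0.05
    n_hubs: int = 5
    hub_degree: int = 60

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_per_group, self.n_background) <= 0:
            raise ValueError("counts must be positive")
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down exceeds n_genes")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not (0 <= self.bimodal_frac <= 1 and 0 <= self.edge_prob <= 1):
            raise ValueError("fractions/probabilities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_expression(config: SimConfig
                        ) -> tuple[ExpressionMatrix, GeneSignature, pd.Series]:
    """Two-condition matrix, the planted ground-truth signature, and labels.

    Signature genes sit at the mid-baseline in the control group and are
    shifted by ±effect in the "autonomous" group; background genes carry no
    group information by construction.
    """
    rng = np.random.default_rng(config.seed)
    n_sig = config.n_up + config.n_down
    n_bg = config.n_genes - n_sig
    n_a = n_b = config.n_per_group
    mid = (config.baseline_low + config.baseline_high) / 2.0

    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    samples = ([f"A{i:03d}" for i in range(1, n_a + 1)]
               + [f"B{i:03d}" for i in range(1, n_b + 1)])

    means = np.empty((config.n_genes, n_a + n_b))
    # planted signature genes: condition-dependent shift
    means[:config.n_up, :n_a] = mid + config.effect
    means[:config.n_up, n_a:] = mid
    means[config.n_up:n_sig, :n_a] = mid - config.effect
    means[config.n_up:n_sig, n_a:] = mid

    # background genes: no group information; a subset is bimodal high/low
    n_bimodal = int(round(config.bimodal_frac * n_bg))
    bimodal_rows = np.arange(n_sig, n_sig + n_bimodal)
    flat_rows = np.arange(n_sig + n_bimodal, config.n_genes)
    if bimodal_rows.size:
        modes = rng.random((bimodal_rows.size, n_a + n_b)) < 0.5
        means[bimodal_rows] = np.where(modes, config.baseline_high,
                                       config.baseline_low)
    if flat_rows.size:
        base = rng.uniform(config.baseline_low, config.baseline_high,
                           size=flat_rows.size)
        means[flat_rows] = base[:, None]

    values = means + rng.normal(0.0, config.noise_sd, size=means.shape)
    lab_a, lab_b = config.group_labels
    groups = pd.Series([lab_a] * n_a + [lab_b] * n_b, index=samples, name="group")
    annotations = groups.to_frame()
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        annotations=annotations, log_scale=True)
    entries = ([(g, 1) for g in genes[:config.n_up]]
               + [(g, -1) for g in genes[config.n_up:n_sig]])
    signature = GeneSignature(name="planted", entries=entries)
    return matrix, signature, groups


def simulate_counts(config: SimConfig) -> ExpressionMatrix:
    """Poisson counts with log-normal rates, for exercising the log-CPM path."""
    rng = np.random.default_rng(config.seed)
    log_means = rng.uniform(config.baseline_low, config.baseline_high,
                            size=(config.n_genes, 2 * config.n_per_group))
    counts = rng.poisson(2.0 ** (log_means + rng.normal(
        0, config.noise_sd, size=log_means.shape)))
    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    samples = [f"S{i:03d}" for i in range(1, 2 * config.n_per_group + 1)]
    return ExpressionMatrix(values=pd.DataFrame(counts, index=genes,
                                                columns=samples, dtype=float),
                            log_scale=False)


def simulate_survival(scores: pd.Series, baseline_hazard: float = 0.1,
                      beta: float = 1.5, censor_rate: float = 0.02,
                      seed: int = 0) -> pd.DataFrame:
    """Exponential survival linked to a composite score.

    Event rate per subject is baseline_hazard * exp(beta * z) with z the
    standardised score; censoring times are independent exponentials at
    ``censor_rate`` (0 disables censoring). Returns a DataFrame indexed by
    subject with columns time, event.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    s = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    sd = s.std(ddof=0)
    z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    rng = np.random.default_rng(seed)
    rate = baseline_hazard * np.exp(beta * z)
    event_time = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=s.size)
    else:
        censor_time = np.full(s.size, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=scores.index)


def simulate_graph(config: SimConfig) -> tuple[nx.Graph, list[str]]:
    """ER background plus planted hubs; returns (graph, hub node ids)."""
    n_total = config.n_background + config.n_hubs
    if config.n_hubs > 0 and config.hub_degree >= n_total:
        raise ValueError("hub_degree must be smaller than the node count")
    rng = np.random.default_rng(config.seed)
    bg = [f"P{i:04d}" for i in range(1, config.n_background + 1)]
    hubs = [f"HUB{i:02d}" for i in range(1, config.n_hubs + 1)]
    g = nx.Graph()
    g.add_nodes_from(bg)
    g.add_nodes_from(hubs)
    n_bg = len(bg)
    iu, ju = np.triu_indices(n_bg, k=1)
    keep = rng.random(iu.size) < config.edge_prob
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(bg[i], bg[j])
    for hub in hubs:
        others = [v for v in bg + hubs if v != hub]
        targets = rng.choice(len(others), size=config.hub_degree, replace=False)
        for t in targets:
            g.add_edge(hub, others[t])
    return g, hubs
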