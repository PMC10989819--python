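"""Synthetic case/control cohorts with planted ground truth.

The generator emulates the statistical structure of a shotgun-metagenomic
case/control study at the species level: sparse compositional abundance
rows that sum to 1, a minority of features carrying disease signal, a
directed dependency structure among features, and clinical covariates
(FBG, BMI, age, weight) monotonically coupled to a marker subset.

Effects are planted on latent log-abundances before compositional
closure, so realised effect sizes on the simplex are attenuated relative
to the nominal log-scale shift.

Two kinds of signal-carrying markers are planted:

* *shifted* markers receive a group-dependent mean shift on the log
  scale, so they differ marginally between cases and controls;
* *flat* markers carry their signal in the second moment: cases have an
  inflated log-scale spread (sd 1 + effect_size vs 1) around the same
  centre.  A rank test on location sees nothing — the median and the
  stochastic ordering P(case > control) = 1/2 are preserved — yet
  threshold-based learners (trees, the NN) can exploit the widened
  tails, so the marker is predictive without a marginal shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .profiles_io import AbundanceProfile, SampleMetadata

logger = logging.getLogger(__name__)

#: default covariate coupling: name -> (noise_sd on the unit-variance
#: signal scale, case shift in output units, output location, output scale)
DEFAULT_COVARIATES = {
    # FBG is the least-noisy covariate (signal:noise variance ratio 2:1)
    # and is additionally elevated in cases, mimicking hyperglycemia.
    "fbg": {"noise_sd": 0.707, "case_shift": 1.5, "loc": 6.0, "scale": 1.2},
    "bmi": {"noise_sd": 1.0, "case_shift": 0.0, "loc": 25.0, "scale": 3.0},
    "age": {"noise_sd": 1.2, "case_shift": 0.0, "loc": 52.0, "scale": 9.0},
    "weight": {"noise_sd": 1.5, "case_shift": 0.0, "loc": 70.0, "scale": 11.0},
}


@dataclass
class CohortConfig:
    """Parameters of a simulated case/control cohort.

    Defaults approximate a mid-sized human-cohort study: a few hundred
    samples, a couple of hundred species-level features of which a tenth
    carry disease signal with a log-scale shift of one standard deviation.
    """

    n_case: int = 100
    n_control: int = 100
    n_features: int = 200
    n_markers: int = 20
    frac_flat_markers: float = 0.0
    effect_size: float = 1.0
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    covariate_spec: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATES.items()})
    sparsity: float = 0.2
    base_mu_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_case, self.n_control, self.n_features) < 1:
            raise ValueError("n_case, n_control and n_features must be positive")
        if not 0 <= self.n_markers <= self.n_features:
            raise ValueError(
                f"n_markers={self.n_markers} must be in [0, {self.n_features}]")
        if not 0.0 <= self.frac_flat_markers <= 1.0:
            raise ValueError("frac_flat_markers must be in [0, 1]")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must be in [0, 1)")
        for s, t, _ in self.planted_edges:
            if not (0 <= s < self.n_features and 0 <= t < self.n_features):
                raise ValueError(f"planted edge ({s}, {t}) outside feature range")


@dataclass
class PlantedTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    marker_indices: list[int]
    flat_marker_indices: list[int]
    marker_signs: dict[int, int]            # shifted markers: +1 case-enriched
    edges: list[tuple[int, int, float]]
    covariate_weights: dict[str, dict[int, float]]

    @property
    def shifted_marker_indices(self) -> list[int]:
        flat = set(self.flat_marker_indices)
        return [m for m in self.marker_indices if m not in flat]


def generate_cohort(config: CohortConfig
                    ) -> tuple[AbundanceProfile, list[SampleMetadata], PlantedTruth]:
    """Simulate a case/control cohort with planted markers and dependencies.

    Returns the compositional profile (rows closed to sum 1), per-sample
    metadata (label + covariates) and the planted ground truth.  Fully
    reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    p = config.n_features
    is_case = np.zeros(n, dtype=bool)
    is_case[:config.n_case] = True

    # latent standard-normal log-scale residuals
    z = rng.standard_normal((n, p))
    base_mu = rng.normal(0.0, config.base_mu_sd, size=p)

    markers = sorted(rng.choice(p, size=config.n_markers, replace=False).tolist())
    n_flat = int(round(config.frac_flat_markers * config.n_markers))
    flat = sorted(rng.choice(markers, size=n_flat, replace=False).tolist())
    flat_set = set(flat)
    shifted = [m for m in markers if m not in flat_set]

    signs = {m: int(rng.choice([-1, 1])) for m in shifted}
    half = config.effect_size / 2.0
    for m in shifted:
        z[is_case, m] += half * signs[m]
        z[~is_case, m] -= half * signs[m]

    # flat markers: same centre, case-inflated spread (scale-only signal)
    for m in flat:
        z[is_case, m] *= 1.0 + config.effect_size

    # planted directed dependencies, applied in topological order
    if config.planted_edges:
        g = nx.DiGraph()
        g.add_nodes_from(t for e in config.planted_edges for t in e[:2])
        g.add_weighted_edges_from(config.planted_edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("planted_edges must form a DAG")
        coef = {(s, t): c for s, t, c in config.planted_edges}
        for node in nx.topological_sort(g):
            for parent in g.predecessors(node):
                z[:, node] += coef[(parent, node)] * z[:, parent]

    # exponentiate, sparsify, close rows to the simplex
    x = np.exp(base_mu[None, :] + z)
    if config.sparsity > 0:
        x[rng.random((n, p)) < config.sparsity] = 0.0
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    for i in zero_rows:   # pathological only at extreme sparsity
        x[i, rng.integers(p)] = 1.0
    x /= x.sum(axis=1, keepdims=True)

    # covariates: weighted sum of the coupled markers' standardized
    # observed abundances + Gaussian noise.  Coupling on the observable
    # (closed) scale keeps noise_sd an exact SNR control: closure hides
    # the absolute latent scale, so a covariate tied to raw latents
    # would carry mostly unrecoverable variance.  Weights take the sign
    # of each marker's planted disease direction, so the covariate rises
    # with case-enriched markers.
    covariate_weights: dict[str, dict[int, float]] = {}
    metadata_cov: dict[str, np.ndarray] = {}
    for name, spec in config.covariate_spec.items():
        coupled = spec.get("markers", markers)
        if not coupled:
            raise ValueError(f"covariate {name!r} coupled to no markers")
        w = {m: signs.get(m, 1) / np.sqrt(len(coupled)) for m in coupled}
        covariate_weights[name] = w
        signal = np.zeros(n)
        for m, wm in w.items():
            col = x[:, m]
            sd = col.std()
            if sd > 0:
                signal += wm * (col - col.mean()) / sd
        if signal.std() == 0:
            raise ValueError(f"covariate {name!r} has a degenerate signal")
        signal /= signal.std()
        raw = signal + rng.normal(0.0, spec["noise_sd"], size=n)
        raw = raw + np.where(is_case, spec.get("case_shift", 0.0), 0.0)
        metadata_cov[name] = spec.get("loc", 0.0) + spec.get("scale", 1.0) * raw

    sample_ids = ([f"case_{i+1:04d}" for i in range(config.n_case)]
                  + [f"ctrl_{i+1:04d}" for i in range(config.n_control)])
    feature_ids = [f"sp_{j+1:04d}" for j in range(p)]
    profile = AbundanceProfile(sample_ids, feature_ids, x)
    metadata = [
        SampleMetadata(sample_id=sid, label=int(is_case[i]),
                       covariates={k: float(v[i]) for k, v in metadata_cov.items()})
        for i, sid in enumerate(sample_ids)
    ]
    truth = PlantedTruth(marker_indices=markers, flat_marker_indices=flat,
                         marker_signs=signs, edges=list(config.planted_edges),
                         covariate_weights=covariate_weights)
    return profile, metadata, truth


def generate_network_data(edges: list[tuple[int, int, float]], n_features: int,
                          n_samples: int, noise_sd: float = 0.25,
                          seed: int = 0) -> np.ndarray:
    """Sample a linear-Gaussian system on a planted DAG.

    Root features are standard normal; every other feature is the
    coefficient-weighted sum of its parents plus Gaussian(0, noise_sd)
    noise.  Cyclic edge lists are rejected.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    g = nx.DiGraph()
    g.add_nodes_from(range(n_features))
    for s, t, _ in edges:
        if not (0 <= s < n_features and 0 <= t < n_features):
            raise ValueError(f"edge ({s}, {t}) outside feature range")
    g.add_weighted_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("edge list contains a cycle")
    coef = {(s, t): c for s, t, c in edges}
    rng = np.random.default_rng(seed)
    x = np.zeros((n_samples, n_features))
    for node in nx.topological_sort(g):
        parents = list(g.predecessors(node))
        if parents:
            x[:, node] = sum(coef[(pa, node)] * x[:, pa] for pa in parents)
            x[:, node] += rng.normal(0.0, noise_sd, size=n_samples)
        else:
            x[:, node] = rng.standard_normal(n_samples)
    return x
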