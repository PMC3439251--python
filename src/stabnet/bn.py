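"""Hybrid discrete/continuous Bayesian network for protein stability.

The joint distribution factorizes over the network as
``P(X_1..X_N) = prod_i P(X_i | pa(X_i))``. Three conditional families are
supported:

* ``cpt`` — an explicit conditional probability table over Boolean parents;
* ``noisy_or`` — a Boolean child whose active parents each independently
  fail to activate it with probability ``q_i``, with a leak ``c0``:
  ``P(child=1 | active set S) = 1 - (1 - c0) * prod_{i in S} q_i``;
* ``gaussian`` — a continuous leaf with one Boolean parent and one
  (mean, variance) Gaussian per parent state (a Gaussian density table).

The canonical stability network has a Stability node conditioned on
N-terminal degron status and three latent summary nodes (PTM, Domain,
Disorder), which in turn aggregate 4 + 9 + 2 observable flags; continuous
leaves carry the sequence-SVM score (child of Stability) and the two
phosphosite PWM scores (children of the two phosphorylation flags).
Inference is exact: unobserved discrete nodes are summed out by
enumeration (the network is small), with continuous evidence entering as
density weights. Parameters are learned by (MAP) expectation-maximization
with Laplace-smoothed tables, a numerically maximized noisy-OR M-step and
posterior-weighted Gaussian moments.

Missing values: discrete evidence arrays use ``-1`` for "unobserved",
continuous arrays use ``NaN`` for "absent".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .features import DISORDER_FEATURES, DOMAIN_FEATURES, PTM_FEATURES, FeatureVector

KIND_CPT = "cpt"
KIND_NOISY_OR = "noisy_or"
KIND_GAUSSIAN = "gaussian"
VARIANTS = ("svm", "bn", "bn_svm")

VARIANCE_FLOOR = 1e-6
_PROB_EPS = 1e-12

MISSING = -1

STABILITY = "stability"
N_TERM = "n_term_stabilizing"
PTM_LATENT = "ptm"
DOMAIN_LATENT = "domain"
DISORDER_LATENT = "disorder"
SVM_LEAF = "svm_score"
PWM_LEAVES = {"tyrosine": "pwm_tyrosine", "ser_thr": "pwm_ser_thr"}


class EmError(RuntimeError):
    """Raised when an EM step decreases the training objective."""


@dataclass(frozen=True)
class Node:
    name: str
    kind: str
    parents: tuple[str, ...] = ()


@dataclass(frozen=True)
class NetworkSpec:
    """Node set, parent map and variant tag; topologically ordered."""

    nodes: tuple[Node, ...]
    variant: str = "bn_svm"

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        known = set(names)
        for node in self.nodes:
            if node.kind not in (KIND_CPT, KIND_NOISY_OR, KIND_GAUSSIAN):
                raise ValueError(f"{node.name}: unknown kind {node.kind}")
            for p in node.parents:
                if p not in known:
                    raise ValueError(f"{node.name}: unknown parent {p}")
        # Kahn's algorithm: detects cycles and fixes a topological order.
        order = _topological_order(self.nodes)
        object.__setattr__(self, "nodes", tuple(order))
        children: dict[str, int] = {n.name: 0 for n in self.nodes}
        for node in self.nodes:
            for p in node.parents:
                children[p] += 1
        by_name = {n.name: n for n in self.nodes}
        for node in self.nodes:
            if node.kind == KIND_GAUSSIAN:
                if len(node.parents) != 1:
                    raise ValueError(f"{node.name}: continuous nodes take 1 parent")
                if by_name[node.parents[0]].kind == KIND_GAUSSIAN:
                    raise ValueError(f"{node.name}: continuous parents unsupported")
                if children[node.name] > 0:
                    raise ValueError(f"{node.name}: continuous nodes must be leaves")

    def node(self, name: str) -> Node:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    @property
    def discrete_nodes(self) -> tuple[Node, ...]:
        return tuple(n for n in self.nodes if n.kind != KIND_GAUSSIAN)

    @property
    def continuous_nodes(self) -> tuple[Node, ...]:
        return tuple(n for n in self.nodes if n.kind == KIND_GAUSSIAN)


def _topological_order(nodes: Sequence[Node]) -> list[Node]:
    by_name = {n.name: n for n in nodes}
    indeg = {n.name: len(n.parents) for n in nodes}
    kids: dict[str, list[str]] = {n.name: [] for n in nodes}
    for n in nodes:
        for p in n.parents:
            kids[p].append(n.name)
    frontier = sorted(name for name, d in indeg.items() if d == 0)
    order: list[Node] = []
    while frontier:
        name = frontier.pop(0)
        order.append(by_name[name])
        for child in kids[name]:
            indeg[child] -= 1
            if indeg[child] == 0:
                frontier.append(child)
    if len(order) != len(nodes):
        raise ValueError("network contains a cycle")
    return order


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class CptParams:
    table: np.ndarray  # shape (2,)*n_parents + (2,), rows sum to 1

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if not np.allclose(self.table.sum(axis=-1), 1.0, atol=1e-8):
            raise ValueError("CPT rows must sum to 1")
        if np.any(self.table < 0):
            raise ValueError("CPT entries must be non-negative")
        # deterministic 0/1 tables are legal as sampling ground truth; EM
        # always returns smoothed (strictly positive) tables


@dataclass
class NoisyOrParams:
    q: np.ndarray  # per-parent inhibition probabilities in (0, 1]
    c0: float  # leak activation in (0, 1)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if np.any(self.q <= 0) or np.any(self.q > 1):
            raise ValueError("inhibition probabilities must lie in (0, 1]")
        if not (0 <= self.c0 < 1):
            raise ValueError("leak must lie in [0, 1)")


@dataclass
class GaussianTable:
    mean: np.ndarray  # (2,) one mean per parent state
    var: np.ndarray  # (2,) floored variances

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if np.any(self.var < VARIANCE_FLOOR * (1 - 1e-12)):
            raise ValueError("variance below floor")


Parameters = dict[str, Union[CptParams, NoisyOrParams, GaussianTable]]


def noisy_or_prob(params: NoisyOrParams, parent_states: Sequence[int]) -> float:
    """P(child = true | parent activation pattern) under leaky noisy-OR."""
    z = np.asarray(parent_states, dtype=float)
    if z.shape != params.q.shape:
        raise ValueError("parent state vector does not match q")
    return float(1.0 - (1.0 - params.c0) * np.prod(params.q**z))


# ---------------------------------------------------------------------------
# Model construction


def default_schema() -> dict:
    return {
        "n_term": N_TERM,
        "ptm": list(PTM_FEATURES),
        "domain": list(DOMAIN_FEATURES),
        "disorder": list(DISORDER_FEATURES),
    }


def build_model(variant: str, feature_schema: Optional[dict] = None) -> NetworkSpec:
    """Build the network structure for one of the three model variants.

    ``bn_svm`` is the full hybrid model; ``bn`` drops the sequence-SVM
    leaf; ``svm`` keeps only the Stability node with the sequence-SVM leaf.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    schema = feature_schema or default_schema()
    if len(schema["ptm"]) != 4 or len(schema["domain"]) != 9 or len(schema["disorder"]) != 2:
        raise ValueError("schema must name 4 PTM, 9 domain and 2 disorder observables")

    if variant == "svm":
        nodes = [
            Node(STABILITY, KIND_CPT),
            Node(SVM_LEAF, KIND_GAUSSIAN, (STABILITY,)),
        ]
        return NetworkSpec(tuple(nodes), variant=variant)

    nodes = [Node(schema["n_term"], KIND_CPT)]
    nodes += [Node(name, KIND_CPT) for name in schema["ptm"]]
    nodes += [Node(name, KIND_CPT) for name in schema["domain"]]
    nodes += [Node(name, KIND_CPT) for name in schema["disorder"]]
    nodes.append(Node(PTM_LATENT, KIND_NOISY_OR, tuple(schema["ptm"])))
    nodes.append(Node(DOMAIN_LATENT, KIND_NOISY_OR, tuple(schema["domain"])))
    nodes.append(Node(DISORDER_LATENT, KIND_CPT, tuple(schema["disorder"])))
    nodes.append(
        Node(
            STABILITY,
            KIND_CPT,
            (schema["n_term"], PTM_LATENT, DOMAIN_LATENT, DISORDER_LATENT),
        )
    )
    # the two PWM leaves hang off the corresponding phosphorylation flags
    nodes.append(Node(PWM_LEAVES["tyrosine"], KIND_GAUSSIAN, (schema["ptm"][0],)))
    nodes.append(Node(PWM_LEAVES["ser_thr"], KIND_GAUSSIAN, (schema["ptm"][1],)))
    if variant == "bn_svm":
        nodes.append(Node(SVM_LEAF, KIND_GAUSSIAN, (STABILITY,)))
    return NetworkSpec(tuple(nodes), variant=variant)


# ---------------------------------------------------------------------------
# Evidence handling


def vectors_to_data(
    spec: NetworkSpec, vectors: Sequence[FeatureVector], with_labels: bool = True
) -> dict[str, np.ndarray]:
    """Convert feature vectors to the columnar evidence arrays of ``spec``.

    Discrete columns are int8 with -1 for unknown; continuous columns are
    float with NaN for absent. Latent nodes are always unobserved here.
    """
    n = len(vectors)
    data: dict[str, np.ndarray] = {}

    def tri(value) -> int:
        return MISSING if value is None else int(value)

    for node in spec.discrete_nodes:
        col = np.full(n, MISSING, dtype=np.int8)
        for i, v in enumerate(vectors):
            if node.name == STABILITY:
                if with_labels and v.label in ("stable", "unstable"):
                    col[i] = 1 if v.label == "stable" else 0
            elif node.name == N_TERM:
                col[i] = tri(v.n_term_stabilizing)
            elif node.name in v.ptm_flags:
                col[i] = tri(v.ptm_flags[node.name])
            elif node.name in v.domain_flags:
                col[i] = tri(v.domain_flags[node.name])
            elif node.name in v.disorder_flags:
                col[i] = tri(v.disorder_flags[node.name])
            # latent summary nodes stay MISSING
        data[node.name] = col
    for node in spec.continuous_nodes:
        col = np.full(n, np.nan)
        for i, v in enumerate(vectors):
            if node.name == SVM_LEAF:
                if v.svm_score is not None:
                    col[i] = v.svm_score
            else:
                kind = next(k for k, leaf in PWM_LEAVES.items() if leaf == node.name)
                score = v.pwm_scores.get(kind)
                if score is not None:
                    col[i] = score
        data[node.name] = col
    return data


def evidence_to_data(spec: NetworkSpec, evidence: dict) -> dict[str, np.ndarray]:
    """Single-record evidence dict -> columnar arrays (unknown nodes absent)."""
    data: dict[str, np.ndarray] = {}
    for node in spec.discrete_nodes:
        value = evidence.get(node.name)
        if value is not None and value not in (0, 1, True, False):
            raise ValueError(f"{node.name}: evidence value {value!r} outside domain")
        data[node.name] = np.array(
            [MISSING if value is None else int(value)], dtype=np.int8
        )
    for node in spec.continuous_nodes:
        value = evidence.get(node.name)
        data[node.name] = np.array([np.nan if value is None else float(value)])
    extra = set(evidence) - {n.name for n in spec.nodes}
    if extra:
        raise ValueError(f"evidence names unknown nodes: {sorted(extra)}")
    return data


# ---------------------------------------------------------------------------
# Joint probability and exact inference


def _log_gaussian(x, mean, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def joint_log_prob(spec: NetworkSpec, params: Parameters, assignment: dict) -> float:
    """Log joint of a full assignment (continuous leaves may be absent)."""
    total = 0.0
    for node in spec.nodes:
        if node.kind == KIND_GAUSSIAN:
            if node.name not in assignment or assignment[node.name] is None:
                continue  # absent leaf: its factor is marginalized out
            x = float(assignment[node.name])
            parent = int(assignment[node.parents[0]])
            table = params[node.name]
            total += float(_log_gaussian(x, table.mean[parent], table.var[parent]))
            continue
        if node.name not in assignment or assignment[node.name] is None:
            raise ValueError(f"assignment missing discrete node {node.name}")
        value = int(assignment[node.name])
        parent_vals = [int(assignment[p]) for p in node.parents]
        if node.kind == KIND_CPT:
            p1 = float(params[node.name].table[tuple(parent_vals) + (1,)])
        else:
            p1 = noisy_or_prob(params[node.name], parent_vals)
        p1 = min(max(p1, _PROB_EPS), 1.0 - _PROB_EPS)
        total += np.log(p1) if value == 1 else np.log1p(-p1)
    return float(total)


def _node_values(name, data, rows, unobs_index, states):
    """Value array for a node, broadcastable over (records, states)."""
    if name in unobs_index:
        return states[:, unobs_index[name]][None, :]
    return data[name][rows].astype(np.int64)[:, None]


def _group_log_weights(spec, params, data, rows, unobs):
    """Unnormalized log joint for each record x latent-state combination."""
    k = len(unobs)
    states = np.zeros((1, 0), dtype=np.int64)
    if k:
        grid = np.indices((2,) * k).reshape(k, -1).T
        states = grid.astype(np.int64)
    unobs_index = {name: j for j, name in enumerate(unobs)}
    m = len(rows)
    logw = np.zeros((m, max(states.shape[0], 1)))
    for node in spec.nodes:
        if node.kind == KIND_GAUSSIAN:
            x = data[node.name][rows]
            mask = np.isfinite(x)
            if not mask.any():
                continue
            parent = _node_values(node.parents[0], data, rows, unobs_index, states)
            table = params[node.name]
            contrib = _log_gaussian(
                np.where(mask, x, 0.0)[:, None], table.mean[parent], table.var[parent]
            )
            logw = logw + np.where(mask[:, None], contrib, 0.0)
            continue
        child = _node_values(node.name, data, rows, unobs_index, states)
        parents = [_node_values(p, data, rows, unobs_index, states) for p in node.parents]
        if node.kind == KIND_CPT:
            logt = np.log(np.clip(params[node.name].table, _PROB_EPS, 1.0))
            logw = logw + logt[tuple(parents) + (child,)]
        else:
            nor = params[node.name]
            s = np.zeros((1, 1))
            for z, qi in zip(parents, nor.q):
                s = s + z * np.log(qi)
            p1 = np.clip(1.0 - (1.0 - nor.c0) * np.exp(s), _PROB_EPS, 1.0 - _PROB_EPS)
            logw = logw + np.where(child == 1, np.log(p1), np.log1p(-p1))
    return states, np.broadcast_to(logw, (m, max(states.shape[0], 1))).copy()


def _missingness_groups(spec, data):
    names = [n.name for n in spec.discrete_nodes]
    n = len(data[names[0]])
    miss = np.stack([data[name] == MISSING for name in names], axis=1)
    _, inverse = np.unique(miss, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        rows = np.flatnonzero(inverse == g)
        unobs = [name for j, name in enumerate(names) if miss[rows[0], j]]
        yield rows, unobs


def infer_stability(spec: NetworkSpec, params: Parameters, evidence: dict) -> float:
    """P(Stability = stable | evidence) by exact summation.

    Any subset of nodes may be observed; continuous leaves enter as
    density weights and unobserved discrete nodes are summed out.
    """
    if STABILITY in evidence and evidence[STABILITY] is not None:
        raise ValueError("stability must be a query node, not evidence")
    data = evidence_to_data(spec, evidence)
    return float(score_records(spec, params, data)[0])


def score_records(
    spec: NetworkSpec, params: Parameters, data: dict[str, np.ndarray]
) -> np.ndarray:
    """Vectorized ``P(stable | evidence)`` for a batch of records."""
    data = dict(data)
    data[STABILITY] = np.full_like(data[STABILITY], MISSING)
    n = len(data[STABILITY])
    out = np.empty(n)
    for rows, unobs in _missingness_groups(spec, data):
        states, logw = _group_log_weights(spec, params, data, rows, unobs)
        stab_col = unobs.index(STABILITY)
        total = logsumexp(logw, axis=1)
        pos = logsumexp(logw[:, states[:, stab_col] == 1], axis=1)
        out[rows] = np.exp(pos - total)
    return out


def log_likelihood(
    spec: NetworkSpec, params: Parameters, data: dict[str, np.ndarray]
) -> float:
    """Observed-data log-likelihood (unobserved discrete nodes summed out)."""
    total = 0.0
    for rows, unobs in _missingness_groups(spec, data):
        _, logw = _group_log_weights(spec, params, data, rows, unobs)
        total += float(logsumexp(logw, axis=1).sum())
    return total


# ---------------------------------------------------------------------------
# EM training


@dataclass
class EmOptions:
    max_iter: int = 200
    tol: float = 1e-6  # relative change in the training objective
    pseudocount: float = 1.0
    seed: int = 0
    variance_floor: float = VARIANCE_FLOOR
    update_gaussians: bool = True
    #: when False the noisy-OR leak stays at its initial value. A leaky
    #: noisy-OR latent whose only child is Stability is identified only up
    #: to a leak rescaling, so parameter-recovery studies clamp the leak.
    learn_leak: bool = True
    #: nodes whose parameters the M-step leaves at their current values
    #: (e.g. score Gaussians fixed after external calibration, or latent
    #: aggregator CPDs clamped in recovery studies where the profile
    #: likelihood leaves them weakly identified).
    frozen_nodes: tuple = ()


@dataclass
class EmResult:
    params: Parameters
    objective_trace: list[float]  # penalized (MAP) objective, non-decreasing
    loglik_trace: list[float]  # raw observed-data log-likelihood
    n_iter: int = 0
    converged: bool = False
    seed: int = 0


def _log_prior(spec: NetworkSpec, params: Parameters, pseudocount: float) -> float:
    if pseudocount == 0:
        return 0.0
    total = 0.0
    for node in spec.nodes:
        if node.kind == KIND_CPT:
            total += pseudocount * float(np.log(params[node.name].table).sum())
    return total


def init_params(
    spec: NetworkSpec,
    data: dict[str, np.ndarray],
    rng: np.random.Generator,
    options: EmOptions,
) -> Parameters:
    """Seeded initialization.

    Root tables draw near 0.5; multi-parent tables of latent aggregators
    start mildly monotone in the number of active parents, which anchors
    the polarity of each latent (its "true" state means "the aggregated
    evidence is present") — without this the latent labels are only
    identified up to a flip. Gaussian leaves start from the moments of the
    records whose parent is observed, falling back to pooled moments split
    by half a standard deviation.
    """
    params: Parameters = {}
    for node in spec.discrete_nodes:
        k = len(node.parents)
        if node.kind == KIND_NOISY_OR:
            params[node.name] = NoisyOrParams(
                q=rng.uniform(0.3, 0.9, size=k), c0=0.05
            )
            continue
        if k == 0:
            p1 = float(rng.beta(5, 5))
            params[node.name] = CptParams(np.array([1 - p1, p1]))
            continue
        shape = (2,) * k
        table = np.empty(shape + (2,))
        for config in np.ndindex(shape):
            if node.name == STABILITY:
                p1 = 0.5 + rng.uniform(-0.1, 0.1)
            else:
                p1 = 0.25 + 0.5 * (sum(config) / k) + rng.uniform(-0.05, 0.05)
            p1 = min(max(p1, 0.05), 0.95)
            table[config] = (1 - p1, p1)
        params[node.name] = CptParams(table)
    for node in spec.continuous_nodes:
        x = data[node.name]
        mask = np.isfinite(x)
        parent = data[node.parents[0]]
        mean = np.empty(2)
        var = np.empty(2)
        pooled_mean = float(x[mask].mean()) if mask.any() else 0.0
        pooled_sd = float(x[mask].std()) if mask.any() else 1.0
        pooled_sd = max(pooled_sd, np.sqrt(options.variance_floor))
        for s in (0, 1):
            sel = mask & (parent == s)
            if sel.sum() >= 2:
                mean[s] = float(x[sel].mean())
                var[s] = max(float(x[sel].var()), options.variance_floor)
            else:
                mean[s] = pooled_mean + (0.5 if s == 1 else -0.5) * pooled_sd
                var[s] = max(pooled_sd**2, options.variance_floor)
        params[node.name] = GaussianTable(mean=mean, var=var)
    return params


def _noisy_or_m_step(
    weight_table: np.ndarray, current: NoisyOrParams, learn_leak: bool = True
) -> NoisyOrParams:
    """Maximize the expected log-likelihood of one noisy-OR child.

    ``weight_table[config, child]`` holds expected counts over the 2^p
    parent configurations; the objective is smooth, so a bounded
    quasi-Newton search started at the current parameters suffices (no
    closed form exists for the leaky noisy-OR).
    """
    p = current.q.shape[0]
    configs = np.indices((2,) * p).reshape(p, -1).T  # (2^p, p)

    fixed_c0 = np.clip(current.c0, 1e-4, 1.0 - 1e-4)

    def negloglik(theta):
        if learn_leak:
            q, c0 = theta[:p], theta[p]
        else:
            q, c0 = theta, fixed_c0
        s = configs @ np.log(q)
        p1 = np.clip(1.0 - (1.0 - c0) * np.exp(s), _PROB_EPS, 1.0 - _PROB_EPS)
        return -(weight_table[:, 1] @ np.log(p1) + weight_table[:, 0] @ np.log1p(-p1))

    x0 = np.clip(current.q, 1e-4, 1.0)
    bounds = [(1e-4, 1.0)] * p
    if learn_leak:
        x0 = np.concatenate([x0, [fixed_c0]])
        bounds.append((1e-4, 1.0 - 1e-4))
    res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds)
    if res.fun <= negloglik(x0):
        q = res.x[:p]
        c0 = float(res.x[p]) if learn_leak else float(fixed_c0)
        return NoisyOrParams(q=q, c0=c0)
    return current  # keep current params rather than take a worse step


def em_train(
    spec: NetworkSpec,
    data: dict[str, np.ndarray],
    options: Optional[EmOptions] = None,
    initial: Optional[Parameters] = None,
) -> EmResult:
    """Fit network parameters by (MAP) expectation-maximization.

    The E-step computes exact posteriors over all unobserved discrete
    nodes; the M-step re-estimates CPT rows from expected counts plus the
    Laplace pseudocount, noisy-OR parameters by bounded numerical
    maximization, and Gaussian tables from posterior-weighted moments with
    a variance floor. The monitored objective is the penalized (MAP)
    log-likelihood — log-likelihood plus the Dirichlet smoothing prior —
    which EM guarantees non-decreasing; a decrease beyond 1e-9 raises
    :class:`EmError`. With ``pseudocount=0`` the objective is the raw
    observed-data log-likelihood.
    """
    options = options or EmOptions()
    rng = np.random.default_rng(options.seed)
    params = initial if initial is not None else init_params(spec, data, rng, options)
    pc = options.pseudocount

    objective_trace: list[float] = []
    loglik_trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, options.max_iter + 1):
        # --- E-step: expected sufficient statistics
        cpt_counts = {
            n.name: np.zeros((2,) * len(n.parents) + (2,))
            for n in spec.discrete_nodes
            if n.kind == KIND_CPT
        }
        nor_counts = {
            n.name: np.zeros((2,) * len(n.parents) + (2,))
            for n in spec.discrete_nodes
            if n.kind == KIND_NOISY_OR
        }
        gauss_stats = {
            n.name: np.zeros((2, 3))  # per parent state: [weight, wx, wx2]
            for n in spec.continuous_nodes
        }
        loglik = 0.0
        for rows, unobs in _missingness_groups(spec, data):
            states, logw = _group_log_weights(spec, params, data, rows, unobs)
            norm = logsumexp(logw, axis=1, keepdims=True)
            loglik += float(norm.sum())
            w = np.exp(logw - norm)
            unobs_index = {name: j for j, name in enumerate(unobs)}
            for node in spec.discrete_nodes:
                counts = cpt_counts.get(node.name, nor_counts.get(node.name))
                vals = [
                    _node_values(p, data, rows, unobs_index, states)
                    for p in node.parents
                ]
                vals.append(_node_values(node.name, data, rows, unobs_index, states))
                idx = np.zeros((1, 1), dtype=np.int64)
                for v in vals:
                    idx = idx * 2 + v
                idx = np.broadcast_to(idx, w.shape)
                np.add.at(counts.reshape(-1), idx.ravel(), w.ravel())
            for node in spec.continuous_nodes:
                x = data[node.name][rows]
                mask = np.isfinite(x)
                if not mask.any():
                    continue
                parent = np.broadcast_to(
                    _node_values(node.parents[0], data, rows, unobs_index, states),
                    w.shape,
                )
                stats = gauss_stats[node.name]
                xm = np.where(mask, x, 0.0)[:, None]
                wm = w * mask[:, None]
                for s in (0, 1):
                    sel = wm * (parent == s)
                    stats[s, 0] += float(sel.sum())
                    stats[s, 1] += float((sel * xm).sum())
                    stats[s, 2] += float((sel * xm**2).sum())

        objective = loglik + _log_prior(spec, params, pc)
        if objective_trace and objective < objective_trace[-1] - 1e-9:
            raise EmError(
                f"EM objective decreased at iteration {n_iter}: "
                f"{objective_trace[-1]:.10f} -> {objective:.10f}"
            )
        objective_trace.append(objective)
        loglik_trace.append(loglik)
        if len(objective_trace) >= 2:
            prev = objective_trace[-2]
            if abs(objective - prev) <= options.tol * (1.0 + abs(objective)):
                converged = True
                break

        # --- M-step
        new_params: Parameters = {}
        for node in spec.discrete_nodes:
            if node.name in options.frozen_nodes:
                new_params[node.name] = params[node.name]
                continue
            if node.kind == KIND_CPT:
                counts = cpt_counts[node.name] + pc
                new_params[node.name] = CptParams(
                    counts / counts.sum(axis=-1, keepdims=True)
                )
            else:
                table = nor_counts[node.name].reshape(-1, 2)
                new_params[node.name] = _noisy_or_m_step(
                    table, params[node.name], learn_leak=options.learn_leak
                )
        for node in spec.continuous_nodes:
            if not options.update_gaussians or node.name in options.frozen_nodes:
                new_params[node.name] = params[node.name]
                continue
            stats = gauss_stats[node.name]
            old = params[node.name]
            mean = old.mean.copy()
            var = old.var.copy()
            for s in (0, 1):
                wsum = stats[s, 0]
                if wsum > 1e-8:
                    mean[s] = stats[s, 1] / wsum
                    var[s] = max(
                        stats[s, 2] / wsum - mean[s] ** 2, options.variance_floor
                    )
            new_params[node.name] = GaussianTable(mean=mean, var=var)
        params = new_params

    return EmResult(
        params=params,
        objective_trace=objective_trace,
        loglik_trace=loglik_trace,
        n_iter=n_iter,
        converged=converged,
        seed=options.seed,
    )


# ---------------------------------------------------------------------------
# Proteome prediction


def classify_score(score: float, thresholds: tuple[float, float]) -> str:
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError("thresholds must satisfy lo < hi")
    if score < lo:
        return "unstable"
    if score > hi:
        return "stable"
    return "non-assigned"


def predict_proteome(
    spec: NetworkSpec,
    params: Parameters,
    vectors: Sequence[FeatureVector],
    thresholds: tuple[float, float] = (0.2, 0.75),
) -> list[tuple[str, float, str]]:
    """Score every protein and bucket it by the two probability thresholds.

    ``score < lo`` -> unstable, ``score > hi`` -> stable, otherwise
    non-assigned. The smoothed tables guarantee scores strictly inside
    (0, 1), so no protein can receive a degenerate 0/1 score for an
    evidence pattern unseen in training.
    """
    data = vectors_to_data(spec, vectors, with_labels=False)
    scores = score_records(spec, params, data)
    return [
        (v.protein_id, float(s), classify_score(float(s), thresholds))
        for v, s in zip(vectors, scores)
    ]


# ---------------------------------------------------------------------------
# Serialization


def model_to_dict(spec: NetworkSpec, params: Parameters, metadata=None) -> dict:
    doc = {
        "variant": spec.variant,
        "nodes": [
            {"name": n.name, "kind": n.kind, "parents": list(n.parents)}
            for n in spec.nodes
        ],
        "parameters": {},
        "metadata": metadata or {},
    }
    for name, p in params.items():
        if isinstance(p, CptParams):
            doc["parameters"][name] = {"kind": KIND_CPT, "table": p.table.tolist()}
        elif isinstance(p, NoisyOrParams):
            doc["parameters"][name] = {
                "kind": KIND_NOISY_OR,
                "q": p.q.tolist(),
                "c0": p.c0,
            }
        else:
            doc["parameters"][name] = {
                "kind": KIND_GAUSSIAN,
                "mean": p.mean.tolist(),
                "var": p.var.tolist(),
            }
    return doc


def model_from_dict(doc: dict) -> tuple[NetworkSpec, Parameters]:
    spec = NetworkSpec(
        tuple(
            Node(n["name"], n["kind"], tuple(n["parents"])) for n in doc["nodes"]
        ),
        variant=doc["variant"],
    )
    params: Parameters = {}
    for name, p in doc["parameters"].items():
        if p["kind"] == KIND_CPT:
            params[name] = CptParams(np.array(p["table"]))
        elif p["kind"] == KIND_NOISY_OR:
            params[name] = NoisyOrParams(q=np.array(p["q"]), c0=float(p["c0"]))
        else:
            params[name] = GaussianTable(
                mean=np.array(p["mean"]), var=np.array(p["var"])
            )
    return spec, params


def save_model(spec: NetworkSpec, params: Parameters, path, metadata=None) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(spec, params, metadata), fh, indent=1)


def load_model(path) -> tuple[NetworkSpec, Parameters]:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Ancestral sampling (used by the synthetic-fixture generator)


def sample_records(
    spec: NetworkSpec, params: Parameters, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw ``n`` exact ancestral samples from the network."""
    data: dict[str, np.ndarray] = {}
    for node in spec.nodes:  # topological order
        if node.kind == KIND_GAUSSIAN:
            parent = data[node.parents[0]]
            table = params[node.name]
            data[node.name] = rng.normal(
                table.mean[parent], np.sqrt(table.var[parent])
            )
            continue
        if node.kind == KIND_CPT:
            table = params[node.name].table
            if node.parents:
                idx = tuple(data[p] for p in node.parents)
                p1 = table[idx + (1,)]
            else:
                p1 = np.full(n, table[1])
        else:
            nor = params[node.name]
            s = np.zeros(n)
            for p_name, qi in zip(node.parents, nor.q):
                s += data[p_name] * np.log(qi)
            p1 = 1.0 - (1.0 - nor.c0) * np.exp(s)
        data[node.name] = (rng.random(n) < p1).astype(np.int8)
    return data
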