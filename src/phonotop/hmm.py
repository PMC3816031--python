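"""Phone HMMs with Gaussian-mixture emissions and embedded Baum-Welch training.

Each phoneme is modelled by a small HMM whose transition structure is
constrained by a :class:`~phonotop.topology.TopologySpec` mask (Bakis-1,
Bakis-2 or Ergodic) and whose per-state emission density is a diagonal-
covariance Gaussian mixture.  Models carry non-emitting entry and exit
states so that phone HMMs concatenate into sentence-level composite models
for supervised ("embedded") re-estimation and for grammar decoding.

All probability computations run in log space with log-sum-exp.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .corpus import Corpus
from .topology import TopologySpec, build_transition_mask

logger = logging.getLogger(__name__)

LOG_ZERO = -np.inf
_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

@dataclass
class GaussianMixtureEmission:
    """Diagonal-covariance Gaussian mixture: weights (M,), means/variances (M,d)."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.weights.shape[0])

    @property
    def dim(self) -> int:
        return int(self.means.shape[1])

    def validate(self, variance_floor: np.ndarray | float = 0.0) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("negative mixture weight")
        if np.any(self.variances < np.asarray(variance_floor) - 1e-12):
            raise ValueError("variance below floor")

    def component_log_prob(self, x: np.ndarray) -> np.ndarray:
        """Per-component log N(x | mu_m, diag(var_m)); x is (T,d) -> (T,M)."""
        diff = x[:, None, :] - self.means[None, :, :]
        quad = np.sum(diff * diff / self.variances[None, :, :], axis=2)
        logdet = np.sum(np.log(self.variances), axis=1)
        return -0.5 * (self.dim * _LOG_2PI + logdet[None, :] + quad)

    def log_prob(self, x: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            logw = np.log(self.weights)
        return logsumexp(self.component_log_prob(x) + logw[None, :], axis=1)


# ---------------------------------------------------------------------------
# phone HMM and model set
# ---------------------------------------------------------------------------

@dataclass
class PhoneHMM:
    """One phoneme's HMM in HTK layout.

    ``trans`` is (n+2)×(n+2): row 0 the entry distribution, rows 1..n the
    emitting states (their last column is the exit probability), row n+1 the
    non-emitting exit (all zeros).  Disallowed arcs are exactly zero.
    """

    label: str
    spec: TopologySpec
    trans: np.ndarray
    emissions: list[GaussianMixtureEmission]

    @property
    def n_states(self) -> int:
        return self.spec.n_states

    @property
    def mask(self) -> np.ndarray:
        return build_transition_mask(self.spec)

    def validate(self, variance_floor: np.ndarray | float = 0.0) -> None:
        n = self.n_states
        if self.trans.shape != (n + 2, n + 2):
            raise ValueError(f"{self.label}: transition matrix shape mismatch")
        mask = self.mask
        if np.any(self.trans[~mask] != 0.0):
            raise ValueError(f"{self.label}: nonzero probability on masked arc")
        rowsums = self.trans[: n + 1].sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-10):
            raise ValueError(f"{self.label}: transition rows must sum to 1")
        if len(self.emissions) != n:
            raise ValueError(f"{self.label}: one emission per emitting state")
        for e in self.emissions:
            e.validate(variance_floor)

    # pieces used to build composite models
    @property
    def entry_probs(self) -> np.ndarray:
        return self.trans[0, 1 : self.n_states + 1]

    @property
    def internal(self) -> np.ndarray:
        return self.trans[1 : self.n_states + 1, 1 : self.n_states + 1]

    @property
    def exit_probs(self) -> np.ndarray:
        return self.trans[1 : self.n_states + 1, self.n_states + 1]


@dataclass
class ModelSet:
    """Bank of phone HMMs sharing a feature dimension and variance floor."""

    hmms: dict[str, PhoneHMM]
    feature_dim: int
    variance_floor: np.ndarray | float = 1e-8

    def __getitem__(self, label: str) -> PhoneHMM:
        return self.hmms[label]

    @property
    def labels(self) -> list[str]:
        return list(self.hmms)

    def validate(self) -> None:
        for hmm in self.hmms.values():
            hmm.validate(self.variance_floor)
            for e in hmm.emissions:
                if e.dim != self.feature_dim:
                    raise ValueError(f"{hmm.label}: emission dim mismatch")

    def copy(self) -> "ModelSet":
        return copy.deepcopy(self)

    def max_components(self) -> int:
        return max(
            e.n_components for h in self.hmms.values() for e in h.emissions
        )


def uniform_transitions(spec: TopologySpec) -> np.ndarray:
    """Transition matrix with probability spread uniformly over allowed arcs."""
    mask = build_transition_mask(spec)
    trans = np.zeros_like(mask, dtype=float)
    for i in range(spec.n_states + 1):
        row = mask[i]
        if row.any():
            trans[i, row] = 1.0 / row.sum()
    return trans


def build_model_set(
    assignment: dict[str, TopologySpec],
    feature_dim: int,
    n_components: int = 1,
) -> ModelSet:
    """Untrained ModelSet: uniform transitions, standard-normal emissions."""
    if len(set(assignment)) != len(assignment):
        raise ValueError("duplicate phoneme labels")
    hmms = {}
    for label, spec in assignment.items():
        emissions = [
            GaussianMixtureEmission(
                weights=np.full(n_components, 1.0 / n_components),
                means=np.zeros((n_components, feature_dim)),
                variances=np.ones((n_components, feature_dim)),
            )
            for _ in range(spec.n_states)
        ]
        hmms[label] = PhoneHMM(label, spec, uniform_transitions(spec), emissions)
    return ModelSet(hmms=hmms, feature_dim=feature_dim)


# ---------------------------------------------------------------------------
# flat start
# ---------------------------------------------------------------------------

def flat_start(model_set: ModelSet, train: Corpus) -> ModelSet:
    """Initialize every emission to the global data mean/variance.

    Also sets the variance floor to 1e-2 × the global per-dimension variance
    (with a small absolute minimum) and resets transitions to uniform over
    the allowed arcs.  Raises if any model's phoneme never occurs in the
    training transcriptions.
    """
    if len(train) == 0:
        raise ValueError("flat start requires a non-empty training corpus")
    present = train.phones_present()
    missing = [p for p in model_set.labels if p not in present]
    if missing:
        raise ValueError(
            "phoneme(s) absent from training transcriptions: "
            + ", ".join(sorted(missing))
        )

    frames = np.concatenate([s.features for s in train], axis=0)
    if frames.shape[1] != model_set.feature_dim:
        raise ValueError("corpus feature dimension does not match model set")
    gmean = frames.mean(axis=0)
    gvar = frames.var(axis=0)
    floor = np.maximum(1e-2 * gvar, 1e-8)
    var0 = np.maximum(gvar, floor)

    out = model_set.copy()
    out.variance_floor = floor
    for hmm in out.hmms.values():
        hmm.trans = uniform_transitions(hmm.spec)
        for e in hmm.emissions:
            m = e.n_components
            e.weights = np.full(m, 1.0 / m)
            e.means = np.tile(gmean, (m, 1))
            e.variances = np.tile(var0, (m, 1))
    return out


# ---------------------------------------------------------------------------
# composite (sentence-level) models
# ---------------------------------------------------------------------------

class EmissionStack:
    """Emissions of many states stacked into padded arrays for vectorized
    per-frame density evaluation (padding components carry zero weight)."""

    def __init__(self, emissions: list[GaussianMixtureEmission]):
        S = len(emissions)
        max_m = max(e.n_components for e in emissions)
        d = emissions[0].dim
        self._means = np.zeros((S, max_m, d))
        self._vars = np.ones((S, max_m, d))
        self._logw = np.full((S, max_m), LOG_ZERO)
        self._m_per_state = np.zeros(S, dtype=int)
        for s, e in enumerate(emissions):
            m = e.n_components
            self._means[s, :m] = e.means
            self._vars[s, :m] = e.variances
            with np.errstate(divide="ignore"):
                self._logw[s, :m] = np.log(e.weights)
            self._m_per_state[s] = m

    def emission_log_probs(self, x: np.ndarray):
        """Returns (log_b (T,S) state log-densities, comp_lp (T,S,Mmax))."""
        diff = x[:, None, None, :] - self._means[None]
        quad = np.sum(diff * diff / self._vars[None], axis=3)
        logdet = np.sum(np.log(self._vars), axis=2)
        d = x.shape[1]
        comp_lp = -0.5 * (d * _LOG_2PI + logdet[None] + quad)
        log_b = logsumexp(comp_lp + self._logw[None], axis=2)
        return log_b, comp_lp


class CompositeHMM(EmissionStack):
    """Concatenation of phone HMMs into one left-to-right sentence model.

    Cross-phone arcs carry probability exit_k(i) · entry_{k+1}(j), so the
    composite is itself a proper HMM over the pooled emitting states.
    """

    def __init__(self, chain: list[PhoneHMM]):
        if not chain:
            raise ValueError("empty phone chain")
        self.chain = chain
        sizes = [h.n_states for h in chain]
        self.offsets = np.concatenate([[0], np.cumsum(sizes)])[:-1]
        self.n_states = int(sum(sizes))

        S = self.n_states
        pi = np.zeros(S)
        A = np.zeros((S, S))
        exit_p = np.zeros(S)
        for k, h in enumerate(chain):
            o, n = self.offsets[k], h.n_states
            A[o : o + n, o : o + n] = h.internal
            if k == 0:
                pi[o : o + n] = h.entry_probs
            if k + 1 < len(chain):
                nxt = chain[k + 1]
                o2, n2 = self.offsets[k + 1], nxt.n_states
                A[o : o + n, o2 : o2 + n2] = np.outer(
                    h.exit_probs, nxt.entry_probs
                )
            else:
                exit_p[o : o + n] = h.exit_probs
        with np.errstate(divide="ignore"):
            self.log_pi = np.log(pi)
            self.log_A = np.log(A)
            self.log_exit = np.log(exit_p)

        super().__init__([e for h in chain for e in h.emissions])

    def forward(self, log_b: np.ndarray) -> tuple[np.ndarray, float]:
        T = log_b.shape[0]
        alpha = np.empty((T, self.n_states))
        alpha[0] = self.log_pi + log_b[0]
        for t in range(1, T):
            alpha[t] = (
                logsumexp(alpha[t - 1][:, None] + self.log_A, axis=0)
                + log_b[t]
            )
        ll = float(logsumexp(alpha[-1] + self.log_exit))
        return alpha, ll

    def backward(self, log_b: np.ndarray) -> np.ndarray:
        T = log_b.shape[0]
        beta = np.empty((T, self.n_states))
        beta[-1] = self.log_exit
        for t in range(T - 2, -1, -1):
            beta[t] = logsumexp(
                self.log_A + (log_b[t + 1] + beta[t + 1])[None, :], axis=1
            )
        return beta

    def loglik(self, x: np.ndarray) -> float:
        if x.shape[0] == 0:
            raise ValueError("empty feature sequence")
        log_b, _ = self.emission_log_probs(x)
        return self.forward(log_b)[1]


def sequence_loglik(hmm_chain: list[PhoneHMM], features: np.ndarray) -> float:
    """Exact forward log-probability of ``features`` under the phone chain."""
    return CompositeHMM(hmm_chain).loglik(features)


def sample_from_models(
    hmm_chain: list[PhoneHMM],
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    """Draw one feature sequence from a phone chain.

    Returns the (T, d) feature matrix and a frame-level alignment of
    ``(phone_label, position_in_chain, emitting_state_index)`` tuples.
    Deterministic for a fixed seed.
    """
    if not hmm_chain:
        raise ValueError("empty phone chain")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    frames: list[np.ndarray] = []
    alignment: list[tuple[str, int, int]] = []
    for pos, hmm in enumerate(hmm_chain):
        n = hmm.n_states
        state = int(rng.choice(n, p=hmm.entry_probs))
        while True:
            emission = hmm.emissions[state]
            comp = int(rng.choice(emission.n_components, p=emission.weights))
            frame = rng.normal(
                emission.means[comp], np.sqrt(emission.variances[comp])
            )
            frames.append(frame)
            alignment.append((hmm.label, pos, state))
            row = hmm.trans[state + 1, 1:]  # emitting targets + exit
            nxt = int(rng.choice(n + 1, p=row / row.sum()))
            if nxt == n:  # exit
                break
            state = nxt
    return np.asarray(frames), alignment


# ---------------------------------------------------------------------------
# embedded Baum-Welch re-estimation
# ---------------------------------------------------------------------------

class _Accumulators:
    def __init__(self, model_set: ModelSet):
        self.trans: dict[str, np.ndarray] = {}
        self.occ: dict[str, list[np.ndarray]] = {}
        self.x: dict[str, list[np.ndarray]] = {}
        self.xx: dict[str, list[np.ndarray]] = {}
        d = model_set.feature_dim
        for label, hmm in model_set.hmms.items():
            n = hmm.n_states
            self.trans[label] = np.zeros((n + 2, n + 2))
            self.occ[label] = [
                np.zeros(e.n_components) for e in hmm.emissions
            ]
            self.x[label] = [
                np.zeros((e.n_components, d)) for e in hmm.emissions
            ]
            self.xx[label] = [
                np.zeros((e.n_components, d)) for e in hmm.emissions
            ]


def _scaled_forward_backward(
    comp: CompositeHMM, log_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Scaled (linear-space) forward-backward.

    Returns (gamma (T,S), xi summed over t (S,S), log-likelihood), or
    ``None`` when per-frame scaling under/overflows and the caller should
    fall back to the log-space path.  Emission densities are normalized
    per frame by their maximum; the normalizers fold into the scale
    factors and only affect the returned log-likelihood.
    """
    T, S = log_b.shape
    m_t = log_b.max(axis=1)
    if not np.all(np.isfinite(m_t)):
        return None
    btilde = np.exp(log_b - m_t[:, None])
    with np.errstate(over="ignore"):
        pi = np.exp(comp.log_pi)
        A = np.exp(comp.log_A)
        exit_p = np.exp(comp.log_exit)

    ahat = np.empty((T, S))
    c = np.empty(T)
    a = pi * btilde[0]
    c[0] = a.sum()
    if not (np.isfinite(c[0]) and c[0] > 0):
        return None
    ahat[0] = a / c[0]
    for t in range(1, T):
        a = (ahat[t - 1] @ A) * btilde[t]
        c[t] = a.sum()
        if not (np.isfinite(c[t]) and c[t] > 0):
            return None
        ahat[t] = a / c[t]
    e_term = float(ahat[-1] @ exit_p)
    if not (np.isfinite(e_term) and e_term > 0):
        return None
    ll = float(np.log(c).sum() + m_t.sum() + np.log(e_term))

    bhat = np.empty((T, S))
    bhat[-1] = exit_p
    for t in range(T - 2, -1, -1):
        bhat[t] = (A @ (btilde[t + 1] * bhat[t + 1])) / c[t + 1]
    if not np.all(np.isfinite(bhat)):
        return None

    gamma = ahat * bhat / e_term
    w = btilde[1:] * bhat[1:] / (c[1:, None] * e_term)
    xi_sum = A * (ahat[:-1].T @ w)
    return gamma, xi_sum, ll


def _logspace_forward_backward(
    comp: CompositeHMM, log_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Reference log-space E-step statistics (slow but underflow-proof)."""
    alpha, ll = comp.forward(log_b)
    if not np.isfinite(ll):
        T, S = log_b.shape
        return np.zeros((T, S)), np.zeros((S, S)), ll
    beta = comp.backward(log_b)
    gamma = np.exp(alpha + beta - ll)
    T, S = log_b.shape
    xi_sum = np.zeros((S, S))
    for t in range(T - 1):
        log_xi = (
            alpha[t][:, None]
            + comp.log_A
            + (log_b[t + 1] + beta[t + 1])[None, :]
            - ll
        )
        xi_sum += np.exp(log_xi)
    return gamma, xi_sum, ll


def _accumulate_sentence(
    comp: CompositeHMM, x: np.ndarray, acc: _Accumulators
) -> float:
    """One E-step over a sentence; returns its log-likelihood (may be -inf)."""
    log_b, comp_lp = comp.emission_log_probs(x)
    stats = _scaled_forward_backward(comp, log_b)
    if stats is None:
        stats = _logspace_forward_backward(comp, log_b)
    gamma, xi_sum, ll = stats
    if not np.isfinite(ll):
        return ll

    # mixture-component responsibilities: gamma split over components
    with np.errstate(invalid="ignore"):
        comp_post = np.exp(comp_lp + comp._logw[None] - log_b[:, :, None])
    comp_post = np.nan_to_num(comp_post, nan=0.0, posinf=0.0)
    comp_resp = comp_post * gamma[:, :, None]  # (T,S,Mmax)

    chain = comp.chain
    last = len(chain) - 1
    # at T-1 the backward value is the exit probability, so the final
    # gamma row is exactly the exit-arc posterior
    exit_post = gamma[-1]
    for k, hmm in enumerate(chain):
        o, n = comp.offsets[k], hmm.n_states
        sl = slice(o, o + n)
        tacc = acc.trans[hmm.label]
        tacc[1 : n + 1, 1 : n + 1] += xi_sum[sl, sl]
        if k == 0:
            tacc[0, 1 : n + 1] += gamma[0, sl]
        else:
            po, pn = comp.offsets[k - 1], chain[k - 1].n_states
            tacc[0, 1 : n + 1] += xi_sum[po : po + pn, sl].sum(axis=0)
        if k == last:
            tacc[1 : n + 1, n + 1] += exit_post[sl]
        else:
            no, nn = comp.offsets[k + 1], chain[k + 1].n_states
            tacc[1 : n + 1, n + 1] += xi_sum[sl, no : no + nn].sum(axis=1)

        for s in range(n):
            g = o + s
            m = comp._m_per_state[g]
            r = comp_resp[:, g, :m]  # (T, m)
            acc.occ[hmm.label][s] += r.sum(axis=0)
            acc.x[hmm.label][s] += r.T @ x
            acc.xx[hmm.label][s] += r.T @ (x * x)
    return ll


def _update_from_accumulators(
    model_set: ModelSet, acc: _Accumulators, min_occ: float = 1e-6
) -> None:
    floor = np.asarray(model_set.variance_floor)
    for label, hmm in model_set.hmms.items():
        n = hmm.n_states
        mask = hmm.mask
        counts = acc.trans[label]
        for i in range(n + 1):
            total = counts[i].sum()
            if total > min_occ:
                row = np.zeros(n + 2)
                row[mask[i]] = counts[i, mask[i]] / total
                # renormalize over allowed arcs only (masked counts are 0)
                ssum = row.sum()
                if ssum > 0:
                    hmm.trans[i] = row / ssum
        for s, e in enumerate(hmm.emissions):
            occ = acc.occ[label][s]
            total = occ.sum()
            if total <= min_occ:
                continue  # state never visited: keep previous parameters
            new_w = occ / total
            hot = occ > min_occ
            means = e.means.copy()
            variances = e.variances.copy()
            means[hot] = acc.x[label][s][hot] / occ[hot, None]
            ex2 = acc.xx[label][s][hot] / occ[hot, None]
            variances[hot] = np.maximum(ex2 - means[hot] ** 2, floor)
            e.weights = new_w
            e.means = means
            e.variances = variances


def embedded_reestimate(
    model_set: ModelSet,
    train: Corpus,
    n_iter: int = 20,
    tol_per_frame: float = 1e-4,
) -> tuple[ModelSet, list[float]]:
    """Supervised (embedded) Baum-Welch over sentence-level composites.

    Each sentence's phone transcription is concatenated into one composite
    HMM; forward-backward statistics are pooled across sentences and all
    occurrences of a phoneme, then every phone model is re-estimated.
    Returns the updated model set and the per-iteration total data
    log-likelihood, which is non-decreasing (EM monotonicity; evaluated
    before each update).  Sentences with no admissible path (fewer frames
    than the shortest transcription path) are skipped with a warning.
    """
    out = model_set.copy()
    lls: list[float] = []
    total_frames = max(train.total_frames(), 1)
    skipped_any = 0
    for it in range(n_iter):
        acc = _Accumulators(out)
        total_ll = 0.0
        skipped = 0
        for sent in train:
            if not sent.phones:
                raise ValueError("sentence lacks a phone transcription")
            chain = [out.hmms[p] for p in sent.phones]
            comp = CompositeHMM(chain)
            ll = _accumulate_sentence(comp, sent.features, acc)
            if np.isfinite(ll):
                total_ll += ll
            else:
                skipped += 1
        if skipped:
            skipped_any = skipped
            logger.warning(
                "embedded_reestimate: skipped %d zero-probability sentence(s)",
                skipped,
            )
        if skipped == len(train):
            raise ValueError("no trainable sentences (all zero-probability)")
        lls.append(total_ll)
        _update_from_accumulators(out, acc)
        if it > 0 and lls[-1] - lls[-2] < tol_per_frame * total_frames:
            break
    if skipped_any:
        logger.info("training ended with %d skipped sentence(s)", skipped_any)
    return out, lls


# ---------------------------------------------------------------------------
# mixture splitting
# ---------------------------------------------------------------------------

def split_mixtures(
    model_set: ModelSet, target_m: int, perturb: float = 0.2
) -> ModelSet:
    """Grow every state's mixture to ``target_m`` components by binary splits.

    At each stage the heaviest components are duplicated with their means
    perturbed by ±perturb·stddev and weights halved (HTK-style mixing up),
    doubling the count until the target is reached; overshoot is trimmed by
    splitting only as many of the heaviest components as still needed.
    """
    if not (1 <= target_m <= 16):
        raise ValueError("target mixture count must lie in [1, 16]")
    current = model_set.max_components()
    if target_m < current:
        raise ValueError(
            f"cannot shrink mixtures: target {target_m} < current {current}"
        )
    out = model_set.copy()
    for hmm in out.hmms.values():
        for e in hmm.emissions:
            while e.n_components < target_m:
                m = e.n_components
                k = min(m, target_m - m)
                order = np.argsort(-e.weights, kind="stable")[:k]
                w, mu, var = list(e.weights), list(e.means), list(e.variances)
                for idx in sorted(order.tolist()):
                    sd = np.sqrt(var[idx])
                    w_half = w[idx] / 2.0
                    w[idx] = w_half
                    base = mu[idx].copy()
                    mu[idx] = base + perturb * sd
                    w.append(w_half)
                    mu.append(base - perturb * sd)
                    var.append(var[idx].copy())
                e.weights = np.asarray(w)
                e.weights = e.weights / e.weights.sum()
                e.means = np.asarray(mu)
                e.variances = np.asarray(var)
    return out
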