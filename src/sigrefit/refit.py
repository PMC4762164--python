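"""Signature refitting for a single tumor by iterative forward selection.

Given a tumor's 96-context fraction profile ``t`` and a reference signature
matrix ``S`` (k x 96, row-stochastic), the algorithm infers non-negative
weights ``w`` such that the reconstruction ``R = w @ S`` minimizes the sum
of squared errors ``SSE = ||t - w @ S||^2``.  Negative contributions are
disallowed because a mutational process cannot remove mutations.

The procedure:

1.  *Candidate filter* — a signature is discarded when any single context
    carries more than 20 % of its mass but the tumor has zero mutations in
    that context: a process that peaked there would have left a trace.
2.  *Seed* — the single signature with the lowest SSE against the tumor
    profile starts with weight 1.
3.  *Forward selection* — repeatedly, for every candidate signature the
    optimal non-negative weight holding all others fixed is computed (the
    SSE is exactly quadratic in one weight, so the minimizer is closed
    form); the single reassignment giving the lowest overall SSE is
    applied.  Iteration stops when one full step improves the SSE by less
    than a fraction ``error_threshold`` (default 0.001) of the current SSE.
    The threshold is relative: an absolute threshold would halt while the
    fit is still coarse whenever the profile is a broad mixture, because
    each individual weight refinement then moves the SSE only slightly.
4.  *Normalization and cutoff* — weights are normalized to sum to 1, then
    every weight below the cutoff (default 6 %) is zeroed *without*
    renormalizing; the removed mass is reported as the "unknown" fraction,
    so reported weights plus unknown always sum to 1.

Samples with few mutations give noisy 96-bin profiles; a warning is logged
below 50 mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import ContextMatrix
from .signatures import SignatureSet, subset_signatures

logger = logging.getLogger(__name__)


class RefitError(ValueError):
    """Refitting cannot proceed on this input."""


@dataclass(frozen=True)
class RefitConfig:
    """Tuning constants of the refit procedure.

    error_threshold
        Stop iterating when one forward step improves the SSE by less than
        this fraction of the SSE before the step (dimensionless).
    weight_cutoff
        Normalized weights below this fraction are zeroed and their mass
        moved to ``unknown``; calibrated on simulated tumors so that false
        positives fall below it.
    context_filter_threshold
        A signature is excluded up front when a single context exceeding
        this fraction of its definition has zero tumor mass.
    min_mutation_warning
        Log a warning when the sample's mutation count is below this.
    max_iterations
        Hard cap guarding against non-termination on pathological input.
    """

    error_threshold: float = 0.001
    weight_cutoff: float = 0.06
    context_filter_threshold: float = 0.20
    min_mutation_warning: int = 50
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        for name in ("error_threshold", "weight_cutoff", "context_filter_threshold"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise RefitError(f"{name}={v} outside [0, 1)")
        if self.min_mutation_warning < 1:
            raise RefitError("min_mutation_warning must be >= 1")


DEFAULT_CONFIG = RefitConfig()


@dataclass
class RefitResult:
    """Fitted decomposition of one tumor profile.

    ``weights`` maps every signature name in the reference set to its final
    normalized weight (zero when filtered or below the cutoff); ``unknown``
    is the weight mass not attributed to any signature, so
    ``sum(weights) + unknown == 1``.
    """

    sample_id: str
    weights: dict[str, float]
    reconstructed: np.ndarray
    residual: np.ndarray
    sse: float
    unknown: float
    excluded_by_filter: list[str] = field(default_factory=list)
    n_mutations: int | None = None
    iterations: int = 0

    @property
    def nonzero_weights(self) -> dict[str, float]:
        return {k: v for k, v in self.weights.items() if v > 0}


# ---------------------------------------------------------------------------
# algorithm pieces

def filter_candidates(
    t: np.ndarray, S: SignatureSet, threshold: float = 0.20
) -> tuple[list[str], list[str]]:
    """Split signature names into (retained, excluded) for tumor profile ``t``.

    Excluded iff the signature has at least one context with definition
    fraction strictly above ``threshold`` at which the tumor has exactly
    zero mass.
    """
    t = np.asarray(t, dtype=float)
    retained, excluded = [], []
    for name, row in zip(S.names, S.values):
        if np.any((row > threshold) & (t == 0.0)):
            excluded.append(name)
        else:
            retained.append(name)
    return retained, excluded


def _sse(t: np.ndarray, recon: np.ndarray) -> float:
    d = t - recon
    return float(d @ d)


def seed_signature(t: np.ndarray, S_sub: SignatureSet) -> int:
    """Index of the single signature with lowest SSE against ``t`` (ties: lowest index)."""
    if S_sub.k == 0:
        raise RefitError("empty signature set")
    sses = ((S_sub.values - t) ** 2).sum(axis=1)
    return int(np.argmin(sses))  # argmin takes the first minimum


def forward_step(
    t: np.ndarray, S_sub: SignatureSet, w: np.ndarray
) -> tuple[int, float, float]:
    """One forward-selection step: the single best weight reassignment.

    For each signature i, the SSE as a function of w_i alone (others fixed)
    is a quadratic ``||(t - sum_{j!=i} w_j S_j) - w_i S_i||^2`` whose
    non-negative minimizer is ``max(0, <S_i, r_i> / <S_i, S_i>)`` with
    ``r_i`` the partial residual.  Returns (index, new weight, new SSE) of
    the globally best reassignment; the step never increases the SSE
    because keeping the current weight is always admissible.
    """
    V = S_sub.values
    w = np.asarray(w, dtype=float)
    recon = w @ V
    best: tuple[int, float, float] | None = None
    for i in range(S_sub.k):
        partial = recon - w[i] * V[i]          # reconstruction without signature i
        r = t - partial
        denom = V[i] @ V[i]
        wi = max(0.0, float(V[i] @ r) / denom) if denom > 0 else 0.0
        sse_i = _sse(r, wi * V[i])
        if best is None or sse_i < best[2]:   # strict <: ties keep the lowest index
            best = (i, wi, sse_i)
    assert best is not None
    return best


def which_signatures(
    t: np.ndarray,
    S: SignatureSet,
    cfg: RefitConfig = DEFAULT_CONFIG,
    n_mutations: int | None = None,
    sample_id: str = "sample",
) -> RefitResult:
    """Infer signature weights for one tumor fraction profile.

    ``t`` must be a 96-vector of fractions summing to 1 (within 1e-6).
    Raises :class:`RefitError` when every signature is removed by the
    candidate filter, since no fit is then possible.
    """
    t = np.asarray(t, dtype=float)
    if t.shape != (96,):
        raise RefitError(f"profile must be a 96-vector, got shape {t.shape}")
    if abs(t.sum() - 1.0) > 1e-6:
        raise RefitError(f"profile sums to {t.sum():.6g}, expected 1")
    if n_mutations is not None and n_mutations < cfg.min_mutation_warning:
        logger.warning(
            "sample %s has only %d mutations (fewer than %d): the 96-bin "
            "profile is noisy and assigned weights may be unreliable",
            sample_id, n_mutations, cfg.min_mutation_warning,
        )

    retained, excluded = filter_candidates(t, S, cfg.context_filter_threshold)
    if not retained:
        raise RefitError(
            f"sample {sample_id}: no candidate signatures survive the "
            f"{cfg.context_filter_threshold:.0%} context filter"
        )
    S_sub = subset_signatures(S, retained)
    V = S_sub.values

    w = np.zeros(S_sub.k)
    w[seed_signature(t, S_sub)] = 1.0
    sse = _sse(t, w @ V)

    iterations = 0
    while iterations < cfg.max_iterations:
        i, wi, sse_new = forward_step(t, S_sub, w)
        if sse_new > sse:          # cannot happen by construction; guard anyway
            break
        rel_improvement = (sse - sse_new) / sse if sse > 0 else 0.0
        improvement = sse - sse_new
        w[i] = wi
        sse = sse_new
        iterations += 1
        if rel_improvement < cfg.error_threshold:
            break
        # numerical floor: on an exact mixture the SSE decays geometrically
        # toward zero, so the relative improvement never drops below the
        # threshold; stop once the fit is exact to machine precision or
        # progress has stalled in absolute terms far below any meaningful SSE
        if sse < 1e-15 or improvement < 1e-14:
            break
    else:
        raise RefitError(
            f"sample {sample_id}: no convergence in {cfg.max_iterations} steps"
        )

    total = w.sum()
    if total == 0:
        raise RefitError(f"sample {sample_id}: all weights converged to zero")
    w_norm = w / total
    w_norm[w_norm < cfg.weight_cutoff] = 0.0   # cutoff, deliberately no renormalization

    weights = {name: 0.0 for name in S.names}
    for name, wv in zip(S_sub.names, w_norm):
        weights[name] = float(wv)
    reconstructed = w_norm @ V
    residual = t - reconstructed
    return RefitResult(
        sample_id=sample_id,
        weights=weights,
        reconstructed=reconstructed,
        residual=residual,
        sse=float(residual @ residual),
        unknown=float(1.0 - w_norm.sum()),
        excluded_by_filter=excluded,
        n_mutations=n_mutations,
        iterations=iterations,
    )


def reconstruct(weights: dict[str, float], S: SignatureSet) -> np.ndarray:
    """Weighted sum of signature rows; sums to the total weight."""
    out = np.zeros(96)
    for name, wv in weights.items():
        if wv < 0:
            raise RefitError(f"negative weight for {name}")
        out += wv * S.row(name)   # S.row raises KeyError on unknown labels
    return out


# ---------------------------------------------------------------------------
# cohort-level plumbing

def batch_refit(
    T: ContextMatrix,
    S: SignatureSet,
    cfg: RefitConfig = DEFAULT_CONFIG,
    n_mutations: dict[str, int] | None = None,
) -> dict[str, RefitResult | RefitError]:
    """Independent :func:`which_signatures` per sample of a fractions matrix.

    Per-sample failures are captured as the error object under that sample's
    key rather than aborting the rest of the cohort.
    """
    if T.mode != "fractions":
        raise RefitError("batch refitting expects a fractions-mode matrix")
    out: dict[str, RefitResult | RefitError] = {}
    for sample_id in T.sample_ids:
        nm = n_mutations.get(sample_id) if n_mutations else None
        try:
            out[sample_id] = which_signatures(
                T.row(sample_id), S, cfg, n_mutations=nm, sample_id=sample_id
            )
        except RefitError as exc:
            logger.warning("sample %s failed: %s", sample_id, exc)
            out[sample_id] = exc
    return out


def signature_prevalence(results: dict[str, RefitResult | RefitError]) -> pd.Series:
    """Fraction of successfully fitted samples in which each signature is detected."""
    fitted = [r for r in results.values() if isinstance(r, RefitResult)]
    if not fitted:
        raise RefitError("no successful fits")
    names = list(fitted[0].weights)
    detected = pd.DataFrame(
        [[r.weights[n] > 0 for n in names] for r in fitted], columns=names
    )
    return detected.mean(axis=0)


def results_to_frame(results: dict[str, RefitResult | RefitError]) -> pd.DataFrame:
    """Long-format table: sample, signature, weight, plus unknown and sse rows."""
    rows = []
    for sample_id, r in results.items():
        if not isinstance(r, RefitResult):
            continue
        for name, wv in r.weights.items():
            rows.append({"sample": sample_id, "signature": name, "weight": wv})
        rows.append({"sample": sample_id, "signature": "unknown", "weight": r.unknown})
        rows.append({"sample": sample_id, "signature": "sse", "weight": r.sse})
    return pd.DataFrame(rows, columns=["sample", "signature", "weight"])
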