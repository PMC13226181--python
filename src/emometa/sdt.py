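"""Signal-detection layer: type-1 d', confidence binning, meta-d', M-ratio.

The type-1 model is the equal-variance Gaussian SDT observer: two stimulus
classes with unit-variance evidence distributions separated by d', response
by comparison to a criterion c. Hit and false-alarm rates of 0 or 1 are
pulled in by the 1/(2N) rule before the z-transform.

meta-d' expresses metacognitive sensitivity on the d' scale: it is the type-1
sensitivity an ideal observer would need in order to produce the observed
confidence-rating data, holding the type-1 response bias fixed. It is fitted
by maximum likelihood over the response-conditional confidence counts, with
the meta-level type-1 criterion scaled as c' = c * (meta_d / d') and K-1
type-2 criteria per response side. M-ratio = meta_d / d' is metacognitive
efficiency: 1 for an ideal observer, < 1 when confidence is noisier than the
decision itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "DEFAULT_EDGES",
    "SdtCounts",
    "SdtResult",
    "type1_dprime_2afc",
    "type1_dprime_rating",
    "bin_confidence",
    "sdt_counts_from_trials",
    "fit_meta_d",
]

#: Default 1-100 confidence bin edges giving K = 4 levels (a value equal to an
#: edge maps to the higher level).
DEFAULT_EDGES: tuple[int, ...] = (25, 50, 75)


@dataclass
class SdtCounts:
    """Stimulus x response x confidence-level counts for the meta-d' fit.

    ``counts[s, r, j]``: trials with stimulus class ``s`` (0 = low/S1,
    1 = high/S2), response ``r`` (0 = 'low' side, 1 = 'high' side) and
    confidence level ``j`` (0-based; K levels).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3 or self.counts.shape[:2] != (2, 2):
            raise ValueError("counts must have shape (2, 2, K)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def k(self) -> int:
        return self.counts.shape[2]

    def n_per_class(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))


@dataclass
class SdtResult:
    """Fitted type-1 and type-2 sensitivities."""

    d_prime: float
    criterion_c: float
    meta_d: float
    m_ratio: float
    neg_log_lik: float
    converged: bool


def _corrected_rate(k: int, n: int) -> float:
    """Proportion k/n with the 1/(2N) correction applied to 0 and 1."""
    if n <= 0:
        raise ValueError("rate needs at least one trial")
    if k == 0:
        return 1.0 / (2 * n)
    if k == n:
        return 1.0 - 1.0 / (2 * n)
    return k / n


def _dprime_from_rates(hr: float, far: float) -> tuple[float, float]:
    zh, zf = norm.ppf(hr), norm.ppf(far)
    return float(zh - zf), float(-0.5 * (zh + zf))


_HIGH = {"valence": ("valence_response", "pleasant", "valence_class"),
         "arousal": ("arousal_response", "high", "arousal_class")}


def type1_dprime_2afc(trials, meta, dimension: str) -> tuple[float, float]:
    """d' and criterion c for a 2AFC table scored against database classes.

    Hit rate is P('pleasant' | high-valence stimulus) (arousal analogously);
    the false-alarm rate is the same response to low-class stimuli. Rates of
    0/1 are corrected by 1/(2N) per class before the z-transform.
    """
    if dimension not in _HIGH:
        raise ValueError(f"unknown dimension {dimension!r}")
    resp_col, high_label, class_col = _HIGH[dimension]
    classes = trials["stimulus_id"].map(meta.set_index("stimulus_id")[class_col])
    said_high = (trials[resp_col] == high_label).to_numpy()
    is_high = (classes == "high").to_numpy()
    n_high, n_low = int(is_high.sum()), int((~is_high).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("both stimulus classes must be present")
    hr = _corrected_rate(int(np.sum(said_high & is_high)), n_high)
    far = _corrected_rate(int(np.sum(said_high & ~is_high)), n_low)
    return _dprime_from_rates(hr, far)


def type1_dprime_rating(
    ratings, normative_values
) -> tuple[float, float]:
    """d' for a continuous rating task via a double median split.

    Convention: stimulus class = normative value above (vs. not above) the
    median normative value across the participant's stimuli; response =
    own rating above (vs. not above) the participant's median rating. The
    z-difference with 1/(2N) correction is then the usual d'.
    """
    ratings = np.asarray(ratings, dtype=float)
    nv = np.asarray(normative_values, dtype=float)
    if ratings.shape != nv.shape:
        raise ValueError("ratings and normative values must align")
    if np.unique(nv).size < 2:
        raise ValueError("all normative values identical; class split undefined")
    is_high = nv > np.median(nv)
    said_high = ratings > np.median(ratings)
    n_high, n_low = int(is_high.sum()), int((~is_high).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("median split produced an empty stimulus class")
    hr = _corrected_rate(int(np.sum(said_high & is_high)), n_high)
    far = _corrected_rate(int(np.sum(said_high & ~is_high)), n_low)
    return _dprime_from_rates(hr, far)


def bin_confidence(conf, k: int = 4, edges=DEFAULT_EDGES):
    """Discretize 1-100 confidence into K ordinal levels (1..K).

    ``level = 1 + #(edges <= conf)``: a confidence exactly equal to an edge
    maps to the higher level. Accepts scalars or arrays.
    """
    edges = np.asarray(edges, dtype=int)
    if edges.size != k - 1:
        raise ValueError(f"need {k - 1} edges for {k} levels, got {edges.size}")
    if np.any(np.diff(edges) <= 0) or edges[0] < 1 or edges[-1] > 100:
        raise ValueError("edges must be strictly increasing within 1..100")
    arr = np.asarray(conf, dtype=int)
    level = 1 + np.sum(arr[..., None] >= edges, axis=-1)
    return int(level) if np.isscalar(conf) else level


def sdt_counts_from_trials(
    trials, meta, dimension: str, k: int = 4, edges=DEFAULT_EDGES
) -> SdtCounts:
    """Tabulate a 2AFC table into stimulus x response x confidence-level counts."""
    resp_col, high_label, class_col = _HIGH[dimension]
    classes = trials["stimulus_id"].map(meta.set_index("stimulus_id")[class_col])
    s = (classes == "high").to_numpy().astype(int)
    r = (trials[resp_col] == high_label).to_numpy().astype(int)
    lev = bin_confidence(trials[f"{dimension}_confidence"].to_numpy(), k, edges) - 1
    counts = np.zeros((2, 2, k))
    np.add.at(counts, (s, r, lev), 1)
    return SdtCounts(counts)


def _conf_probs(meta_d: float, c1p: float, t2_low: np.ndarray, t2_high: np.ndarray,
                k: int) -> np.ndarray:
    """P(conf level | stimulus, response) under the meta-level observer.

    Returns array of shape (2 stimuli, 2 responses, K levels); rows with an
    (essentially) impossible response get a uniform placeholder, which is
    harmless because such cells carry only padding mass.
    """
    mus = np.array([-meta_d / 2.0, meta_d / 2.0])
    # boundaries for the 'low' response (evidence below c1'): descending conf
    # as evidence approaches c1'
    low_bounds = np.concatenate(([-np.inf], t2_low, [c1p]))
    high_bounds = np.concatenate(([c1p], t2_high, [np.inf]))
    probs = np.empty((2, 2, k))
    for s, mu in enumerate(mus):
        cdf_low = norm.cdf(low_bounds - mu)
        seg_low = np.diff(cdf_low)  # level K ... level 1
        p_low = cdf_low[-1]
        cdf_high = norm.cdf(high_bounds - mu)
        seg_high = np.diff(cdf_high)  # level 1 ... level K
        p_high = 1.0 - cdf_high[0]
        probs[s, 0] = (seg_low[::-1] / p_low) if p_low > 1e-300 else 1.0 / k
        probs[s, 1] = (seg_high / p_high) if p_high > 1e-300 else 1.0 / k
    return probs


def fit_meta_d(
    counts: SdtCounts,
    padding: float | None = None,
    d_bound_scale: float = 5.0,
) -> SdtResult:
    """Maximum-likelihood meta-d' from confidence-rating counts.

    The type-1 parameters (d', c) are estimated from the padded response
    totals with the 1/(2N) correction and then held fixed; meta_d and the
    2(K-1) type-2 criteria are fitted by maximizing the multinomial likelihood
    of the response-conditional confidence counts, with the meta-level type-1
    criterion constrained to c' = c * meta_d / d'.

    Parameters
    ----------
    counts : SdtCounts
    padding : float, optional
        Added to every stimulus x response x level cell before likelihood
        evaluation; defaults to 1/(2K), the standard cell padding that keeps
        empty cells from dominating the fit.
    d_bound_scale : float
        Upper search bound for meta_d is ``d_bound_scale * d' + 1``.

    Returns
    -------
    SdtResult
        With ``converged=False`` (never silently) if no optimizer start
        succeeded.
    """
    c = counts.counts
    k = counts.k
    if padding is None:
        padding = 1.0 / (2 * k)
    resp_totals = c.sum(axis=2)  # (stim, resp)
    if np.any(resp_totals.sum(axis=0) == 0):
        raise ValueError("a response category has zero trials; meta-d' undefined")
    n_s1, n_s2 = c[0].sum(), c[1].sum()
    if n_s1 == 0 or n_s2 == 0:
        raise ValueError("both stimulus classes must be present")
    far = _corrected_rate(int(round(resp_totals[0, 1])), int(round(n_s1)))
    hr = _corrected_rate(int(round(resp_totals[1, 1])), int(round(n_s2)))
    d1, c1 = _dprime_from_rates(hr, far)
    if d1 <= 0:
        raise ValueError("type-1 d' is non-positive; meta-d' model undefined")

    padded = c + padding

    def nll(params: np.ndarray) -> float:
        meta_d = params[0]
        c1p = c1 * meta_d / d1
        # positive gaps stack outward from c1' on each side
        gaps_low = params[1:k]
        gaps_high = params[k : 2 * k - 1]
        t2_low = c1p - np.cumsum(gaps_low)[::-1]  # ascending, below c1'
        t2_high = c1p + np.cumsum(gaps_high)  # ascending, above c1'
        probs = _conf_probs(meta_d, c1p, t2_low, t2_high, k)
        return -float(np.sum(padded * np.log(np.maximum(probs, 1e-300))))

    upper = d_bound_scale * d1 + 1.0
    bounds = [(0.0, upper)] + [(1e-4, 10.0)] * (2 * (k - 1))
    best = None
    for start in (0.5 * d1, d1, 1.5 * d1):
        x0 = np.concatenate(([min(start, upper)], np.full(2 * (k - 1), 0.5)))
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    meta_d = float(best.x[0])
    return SdtResult(
        d_prime=d1,
        criterion_c=c1,
        meta_d=meta_d,
        m_ratio=meta_d / d1,
        neg_log_lik=float(best.fun),
        converged=bool(best.success),
    )
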