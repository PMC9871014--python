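"""Shannon entropy, cross-entropy, and KL divergence for belief vectors.

All quantities are reported in units of ``log_base`` (bits for base 2, the
default; nats for base e). The ``0 log 0 := 0`` convention applies
throughout, matching the limit of x log x as x -> 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr

from .errors import ValidationError


@dataclass(frozen=True)
class EntropyOptions:
    """Conventions for entropy computations.

    Parameters
    ----------
    log_base
        Base of the logarithm; must exceed 1. Base 2 yields bits, base e nats.
    epsilon
        Optional smoothing floor for cross-entropy. When set, candidate
        distributions are floored at ``epsilon`` and renormalized before the
        cross term, so unsupported zeros give a large finite penalty instead
        of +inf. Off by default: flooring silently changes the metric.
    """

    log_base: float = 2.0
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if not self.log_base > 1:
            raise ValidationError(f"log_base must exceed 1; got {self.log_base!r}")
        if self.epsilon is not None and not (0 < self.epsilon <= 1e-3):
            raise ValidationError(
                f"epsilon must lie in (0, 1e-3]; got {self.epsilon!r}"
            )


DEFAULT_OPTIONS = EntropyOptions()


def _plogq(p: np.ndarray, q: np.ndarray, base: float) -> np.ndarray:
    """Elementwise p * log_base(q) with the 0 log 0 convention.

    Entries with p == 0 contribute exactly 0 (even where q == 0); entries
    with p > 0 and q == 0 contribute -inf. Base 2 and base e use the direct
    numpy logarithms so that e.g. the uniform distribution's entropy equals
    log2(K) to the last bit.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        if base == 2.0:
            logq = np.log2(q)
        elif base == math.e:
            logq = np.log(q)
        else:
            logq = np.log(q) / math.log(base)
        out = p * logq
    out = np.where(p == 0.0, 0.0, out)
    return out


def shannon_entropy(p, options: EntropyOptions = DEFAULT_OPTIONS) -> float:
    """Shannon entropy H(p) = -sum_i p_i log p_i, in units of the log base.

    Lies in ``[0, log_base(K)]`` for a K-category distribution; 0 iff p is
    degenerate (one-hot), maximal iff p is uniform.
    """
    p = np.asarray(p, dtype=np.float64)
    return float(-_plogq(p, p, options.log_base).sum())


def cross_entropy(p, q, options: EntropyOptions = DEFAULT_OPTIONS) -> float:
    """Cross-entropy H(p, q) = -sum_i p_i log q_i.

    Returns +inf when q places zero mass where p does not, unless
    ``options.epsilon`` is set, in which case q is floored at epsilon and
    renormalized first. Always >= shannon_entropy(p) (Gibbs' inequality).
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValidationError(
            f"length mismatch: p has shape {p.shape}, q has shape {q.shape}"
        )
    if options.epsilon is not None:
        q = np.maximum(q, options.epsilon)
        q = q / q.sum()
    return float(-_plogq(p, q, options.log_base).sum())


def kl_divergence(p, q, options: EntropyOptions = DEFAULT_OPTIONS) -> float:
    """KL divergence D(p || q) = sum_i p_i log(p_i / q_i), >= 0.

    Zero iff p == q; +inf when q lacks support where p has mass (no epsilon
    smoothing is applied here). Satisfies
    ``kl_divergence(p, q) == cross_entropy(p, q) - shannon_entropy(p)``
    whenever q is strictly positive.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValidationError(
            f"length mismatch: p has shape {p.shape}, q has shape {q.shape}"
        )
    return float(rel_entr(p, q).sum() / math.log(options.log_base))
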