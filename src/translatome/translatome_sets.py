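"""Highly translated gene sets via the Tukey upper fence, and overlap tests.

A gene is called "highly translated" in a condition when its mean Ribo-Seq
TPM lies strictly above the Tukey upper fence of that condition's TPM
distribution: ``threshold = Q3 + k * IQR`` with ``k = 1.5`` by default and
quartiles computed by linear interpolation between order statistics. The
overlap of two cell types' sets against a finite expressed-gene universe is
scored with the upper-tail hypergeometric test, evaluated in log space via
log-gamma so that p-values far below the smallest normal double (overlaps of
real translatomes routinely reach p < 1e-250) remain representable as
``log10_p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .io_formats import ValidationError
from .quantify import ConditionTPM

QUANTILE_METHOD = "linear-interpolation"


@dataclass(frozen=True)
class FenceParams:
    """Tukey fence multiplier and the (fixed) quantile convention."""

    k: float = 1.5
    quantile_method: str = QUANTILE_METHOD

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValidationError("fence multiplier k must be >= 0")
        if self.quantile_method != QUANTILE_METHOD:
            raise ValidationError(
                f"only quantile_method={QUANTILE_METHOD!r} is supported"
            )


@dataclass(frozen=True)
class OutlierResult:
    """Upper-fence threshold and member genes for one condition."""

    condition: str
    q1: float
    q3: float
    iqr: float
    threshold: float
    members: tuple[str, ...]
    quantile_method: str = QUANTILE_METHOD

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene_id": sorted(self.members),
                "condition": self.condition,
                "threshold": self.threshold,
            }
        )


@dataclass(frozen=True)
class VennPartition:
    """Disjoint A-only / B-only / shared blocks of two gene sets."""

    a_only: frozenset[str]
    b_only: frozenset[str]
    shared: frozenset[str]

    @property
    def n_a(self) -> int:
        return len(self.a_only) + len(self.shared)

    @property
    def n_b(self) -> int:
        return len(self.b_only) + len(self.shared)

    def to_frame(self):
        import pandas as pd

        rows = [("a_only", g) for g in sorted(self.a_only)]
        rows += [("b_only", g) for g in sorted(self.b_only)]
        rows += [("shared", g) for g in sorted(self.shared)]
        return pd.DataFrame(rows, columns=["block", "gene_id"])


@dataclass(frozen=True)
class OverlapTest:
    """Upper-tail hypergeometric overlap of two sets in a finite universe."""

    universe_n: int
    n_a: int
    n_b: int
    n_shared: int
    log10_p: float
    p_value: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "universe_n": self.universe_n,
                    "n_a": self.n_a,
                    "n_b": self.n_b,
                    "n_shared": self.n_shared,
                    "log10_p": self.log10_p,
                    "p_value": self.p_value,
                }
            ]
        )


def tukey_upper_fence(
    values, params: FenceParams = FenceParams()
) -> tuple[float, float, float, float]:
    """Quartiles and upper fence ``Q3 + k*IQR`` of a sample.

    Quartiles interpolate linearly between order statistics at zero-based
    position ``(n - 1) * q``. Requires at least 4 finite values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValidationError(f"need >= 4 values for a fence, got {v.size}")
    if np.isnan(v).any():
        raise ValidationError("NaN in fence input")
    if np.isinf(v).any():
        raise ValidationError("non-finite value in fence input")
    q1, q3 = np.quantile(v, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    return float(q1), float(q3), float(iqr), float(q3 + params.k * iqr)


def highly_translated(
    cond: ConditionTPM,
    params: FenceParams = FenceParams(),
    nonzero_only: bool = False,
) -> OutlierResult:
    """Genes of one condition whose mean TPM is strictly above the fence.

    The fence is computed on the condition's full TPM distribution; with
    ``nonzero_only`` genes at TPM 0 are dropped before computing quartiles
    (membership is still decided on all genes — a zero can never exceed an
    upper fence of non-negative data).
    """
    tpm = cond.mean_tpm
    fence_values = tpm[tpm > 0] if nonzero_only else tpm
    q1, q3, iqr, threshold = tukey_upper_fence(fence_values.to_numpy(), params)
    members = tuple(tpm.index[tpm.to_numpy() > threshold])
    return OutlierResult(
        condition=cond.label,
        q1=q1,
        q3=q3,
        iqr=iqr,
        threshold=threshold,
        members=members,
    )


def venn_partition(set_a, set_b) -> VennPartition:
    """Exact set algebra: A-only, B-only and shared blocks of two gene sets."""
    a, b = frozenset(set_a), frozenset(set_b)
    return VennPartition(a_only=a - b, b_only=b - a, shared=a & b)


def _log_hypergeom_upper_tail(universe_n: int, n_a: int, n_b: int, k: int) -> float:
    """Natural-log P(X >= k) for X ~ Hypergeometric(N, K=n_a, n=n_b).

    Summed in log space from log-gamma pmf terms so extreme tails (well
    below the double-precision underflow threshold) keep full relative
    precision in the log.
    """
    lo = max(0, n_a + n_b - universe_n)
    hi = min(n_a, n_b)
    if k <= lo:
        return 0.0
    ks = np.arange(k, hi + 1)
    log_pmf = (
        gammaln(n_a + 1)
        - gammaln(ks + 1)
        - gammaln(n_a - ks + 1)
        + gammaln(universe_n - n_a + 1)
        - gammaln(n_b - ks + 1)
        - gammaln(universe_n - n_a - n_b + ks + 1)
        - (gammaln(universe_n + 1) - gammaln(n_b + 1) - gammaln(universe_n - n_b + 1))
    )
    return float(min(0.0, logsumexp(log_pmf)))


def hypergeometric_overlap(
    universe_n: int, n_a: int, n_b: int, n_shared: int
) -> OverlapTest:
    """Upper-tail hypergeometric test of the overlap of two gene sets.

    Returns both ``log10_p`` (always representable) and a linear ``p_value``
    clipped at the smallest positive double when the true value underflows.
    The test is symmetric in the two sets.
    """
    for name, val in (
        ("universe_n", universe_n),
        ("n_a", n_a),
        ("n_b", n_b),
        ("n_shared", n_shared),
    ):
        if int(val) != val or val < 0:
            raise ValidationError(f"{name} must be a non-negative integer")
    universe_n, n_a, n_b, n_shared = map(int, (universe_n, n_a, n_b, n_shared))
    if n_a > universe_n or n_b > universe_n:
        raise ValidationError("set larger than universe")
    if n_shared > min(n_a, n_b):
        raise ValidationError("shared count exceeds a set size")
    if n_shared < max(0, n_a + n_b - universe_n):
        raise ValidationError("shared count below the forced minimum overlap")
    log_p = _log_hypergeom_upper_tail(universe_n, n_a, n_b, n_shared)
    p = math.exp(log_p)
    if p == 0.0:
        p = math.ulp(0.0)  # smallest positive subnormal; true p is below it
    return OverlapTest(
        universe_n=universe_n,
        n_a=n_a,
        n_b=n_b,
        n_shared=n_shared,
        log10_p=log_p / math.log(10),
        p_value=p,
    )
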