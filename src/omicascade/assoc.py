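"""Univariate association engine.

Every step of the discovery cascade reduces to one of two tests:

* the slope t-test of a simple (univariate) linear regression,
  ``y = a + beta * x``, with genotype entering as an additive 0/1/2 allele
  dosage, and
* the Pearson correlation t-test, optionally gated on the sign of *r*
  (miRNA–mRNA pairs must be negatively correlated to pass).

The two tests are algebraically identical (t = beta/se = r*sqrt((n-2)/(1-r^2)))
and this module computes both from the same centered sums so the equivalence
holds numerically as well.  Missing values are handled by listwise deletion
per test.  Zero-variance (monomorphic) predictors yield a flagged,
non-significant record rather than an exception so genome-wide scans never
abort; exact fits yield the smallest representable p-value with a
``perfect_fit`` flag.

Vectorized variants (:func:`bulk_slope`, :func:`bulk_pearson`) apply the same
formulas column-wise and are what the cascade uses for genome-wide scans; unit
tests pin them to the scalar path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParseError, ValidationError

__all__ = [
    "AssociationRecord",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "encode_additive",
    "fit_slope",
    "pearson_with_sign",
    "bulk_slope",
    "bulk_pearson",
    "MIN_P",
]

#: Smallest positive double; reported instead of 0.0 for exact fits.
MIN_P = float(np.nextafter(0.0, 1.0))

_MIN_N = 3  # complete cases required for a slope test (n - 2 >= 1 df)


# ---------------------------------------------------------------------------
# records and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationRecord:
    """Result of one univariate association test.

    ``flags`` may contain ``"degenerate"`` (zero-variance input, p forced to
    1) or ``"perfect_fit"`` (zero residual, p forced to the smallest
    representable double).  ``passed`` is populated only when the caller
    supplied a threshold (and, for sign-gated correlations, the required
    sign).
    """

    x_id: str
    y_id: str
    step_label: str | None
    n: int
    beta: float
    se: float
    t: float
    p: float
    r: float | None = None
    passed: bool | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p-value {self.p} outside [0, 1]")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive genotype calls.

    ``calls`` holds float dosages in {0, 1, 2} with NaN for missing.  The
    coded allele is the alternate (non-reference) allele, so the per-SNP
    ``allele_freq`` is the coded-allele frequency
    sum(calls) / (2 * number of non-missing calls).
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy(dtype=float, copy=False)
        bad = np.isfinite(vals) & ~np.isin(vals, (0.0, 1.0, 2.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype call {vals[i, j]!r} at sample "
                f"{self.calls.index[i]!r}, SNP {self.calls.columns[j]!r} "
                "is not in {0, 1, 2, missing}"
            )
        if self.calls.index.has_duplicates:
            dups = self.calls.index[self.calls.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if self.calls.columns.has_duplicates:
            dups = self.calls.columns[self.calls.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate SNP ids: {dups}")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def allele_freq(self) -> pd.Series:
        """Coded-allele frequency per SNP, ignoring missing calls."""
        return self.calls.sum(skipna=True) / (2.0 * self.calls.notna().sum())


@dataclass
class ExpressionMatrix:
    """Samples x features continuous (log-scale) expression values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample or feature ids")
        empty = self.values.columns[self.values.isna().all(axis=0)]
        if len(empty):
            raise ValidationError(
                f"entirely-missing feature columns: {list(empty)}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# genotype encoding
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "NA", "NN", "--", ".", "./.", ".|."}


def encode_additive(
    calls: Iterable, coded_allele: str | None = None
) -> np.ndarray:
    """Encode genotype calls as additive 0/1/2 dosages of the coded allele.

    Accepts, per element: numeric dosages (0, 1, 2, NaN), VCF GT strings
    ("0/0", "0|1", "./."), or two-letter genotypes ("AA", "AG") together
    with the ``coded_allele`` (the alternate allele whose copies are
    counted).  Missing markers propagate as NaN.
    """
    out: list[float] = []
    for call in calls:
        if call is None or (isinstance(call, float) and np.isnan(call)):
            out.append(np.nan)
            continue
        if isinstance(call, (int, np.integer, float, np.floating)):
            v = float(call)
            if v not in (0.0, 1.0, 2.0):
                raise ParseError(f"unrecognized genotype call {call!r}")
            out.append(v)
            continue
        s = str(call).strip()
        if s in _MISSING_TOKENS:
            out.append(np.nan)
            continue
        if s in ("0", "1", "2"):
            out.append(float(s))
            continue
        if "/" in s or "|" in s:  # VCF GT
            alleles = s.replace("|", "/").split("/")
            if "." in alleles:
                out.append(np.nan)
            elif set(alleles) <= {"0", "1"}:
                out.append(float(sum(a == "1" for a in alleles)))
            else:
                raise ParseError(f"unrecognized genotype call {s!r}")
            continue
        if len(s) == 2 and s.isalpha():  # letter genotype, e.g. "AG"
            if coded_allele is None:
                raise ParseError(
                    f"letter genotype {s!r} requires a coded_allele"
                )
            out.append(float(sum(a == coded_allele for a in s.upper())))
            continue
        raise ParseError(f"unrecognized genotype call {s!r}")
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# scalar tests
# ---------------------------------------------------------------------------

def _centered_sums(x: np.ndarray, y: np.ndarray):
    xc = x - x.mean()
    yc = y - y.mean()
    return xc @ xc, yc @ yc, xc @ yc


def _var_floor(v: np.ndarray) -> float:
    # centered sum-of-squares below this is numerically zero
    scale = max(1.0, float(np.abs(v).max(initial=0.0)))
    return v.size * (np.finfo(float).eps * scale) ** 2 * 4.0


def _complete_cases(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError(
            f"length mismatch: x has {x.size}, y has {y.size}"
        )
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def fit_slope(
    x,
    y,
    *,
    x_id: str = "x",
    y_id: str = "y",
    step_label: str | None = None,
    alpha: float | None = None,
) -> AssociationRecord:
    """OLS slope of y on x with the two-sided t-test on the slope.

    Missing pairs are listwise-deleted.  A zero-variance predictor or
    constant response yields a flagged record with p = 1 instead of raising,
    so scans over monomorphic SNPs keep going.
    """
    xv, yv = _complete_cases(x, y)
    n = xv.size
    if n < _MIN_N:
        raise InsufficientDataError(
            f"{n} complete cases for ({x_id}, {y_id}); need >= {_MIN_N}"
        )
    sxx, syy, sxy = _centered_sums(xv, yv)
    if sxx <= _var_floor(xv) or syy <= _var_floor(yv):
        return AssociationRecord(
            x_id, y_id, step_label, n,
            beta=0.0, se=float("nan"), t=0.0, p=1.0, r=None,
            passed=False if alpha is not None else None,
            flags=("degenerate",),
        )
    beta = sxy / sxx
    r = sxy / np.sqrt(sxx * syy)
    df = n - 2
    sse = syy - beta * sxy
    if sse <= syy * 1e-14:  # exact linear relationship
        return AssociationRecord(
            x_id, y_id, step_label, n,
            beta=float(beta), se=0.0,
            t=float(np.copysign(np.inf, beta)), p=MIN_P, r=float(r),
            passed=True if alpha is not None else None,
            flags=("perfect_fit",),
        )
    se = np.sqrt(sse / df / sxx)
    t = beta / se
    p = max(2.0 * float(stats.t.sf(abs(t), df)), MIN_P)
    return AssociationRecord(
        x_id, y_id, step_label, n,
        beta=float(beta), se=float(se), t=float(t), p=p, r=float(r),
        passed=(p <= alpha) if alpha is not None else None,
    )


def pearson_with_sign(
    x,
    y,
    required_sign: str = "any",
    *,
    x_id: str = "x",
    y_id: str = "y",
    step_label: str | None = None,
    alpha: float | None = None,
) -> AssociationRecord:
    """Pearson correlation with its t-transform p-value and optional sign gate.

    With ``required_sign="negative"`` the record passes only when r < 0 and
    (if ``alpha`` is given) p <= alpha — the repressive-regulation filter
    used for miRNA–mRNA pairs.
    """
    if required_sign not in ("any", "negative"):
        raise ValidationError(f"required_sign {required_sign!r} unknown")
    rec = fit_slope(
        x, y, x_id=x_id, y_id=y_id, step_label=step_label, alpha=alpha
    )
    if "degenerate" in rec.flags:
        return AssociationRecord(
            rec.x_id, rec.y_id, rec.step_label, rec.n,
            beta=rec.beta, se=rec.se, t=rec.t, p=rec.p, r=rec.r,
            passed=False, flags=rec.flags,
        )
    passed = rec.passed
    if required_sign == "negative":
        passed = bool(rec.r is not None and rec.r < 0.0) and (
            alpha is None or rec.p <= alpha
        )
    return AssociationRecord(
        rec.x_id, rec.y_id, rec.step_label, rec.n,
        beta=rec.beta, se=rec.se, t=rec.t, p=rec.p, r=rec.r,
        passed=passed, flags=rec.flags,
    )


# ---------------------------------------------------------------------------
# vectorized scans
# ---------------------------------------------------------------------------

def bulk_slope(X: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    """Slope test of y on every column of X (NaN-aware, listwise per column).

    Returns arrays ``beta, se, t, p, r, n`` plus boolean masks ``degenerate``
    (zero-variance column or response, or n < 3; p forced to 1) and
    ``perfect`` (zero residual; p forced to the minimum representable value).
    Same formulas as :func:`fit_slope`, applied column-wise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.size:
        raise ValidationError(
            f"row mismatch: X has {X.shape[0]}, y has {y.size}"
        )
    M = np.isfinite(X) & np.isfinite(y)[:, None]
    n = M.sum(axis=0)
    ok_n = n >= _MIN_N
    nf = np.where(ok_n, n, _MIN_N).astype(float)

    Xz = np.where(M, X, 0.0)
    Yz = np.where(M, y[:, None], 0.0)
    mx = Xz.sum(axis=0) / nf
    my = Yz.sum(axis=0) / nf
    Xc = np.where(M, X - mx, 0.0)
    Yc = np.where(M, y[:, None] - my, 0.0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    syy = np.einsum("ij,ij->j", Yc, Yc)
    sxy = np.einsum("ij,ij->j", Xc, Yc)

    xmax = np.maximum(1.0, np.abs(Xz).max(axis=0))
    ymax = max(1.0, float(np.abs(Yz).max(initial=0.0)))
    floor_x = nf * (np.finfo(float).eps * xmax) ** 2 * 4.0
    floor_y = nf * (np.finfo(float).eps * ymax) ** 2 * 4.0
    degenerate = (~ok_n) | (sxx <= floor_x) | (syy <= floor_y)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(degenerate, 0.0, sxy / np.where(sxx > 0, sxx, 1.0))
        r = sxy / np.sqrt(np.where(degenerate, 1.0, sxx * syy))
        r = np.where(degenerate, np.nan, r)
        df = np.maximum(n - 2, 1)
        sse = syy - beta * sxy
        perfect = (~degenerate) & (sse <= syy * 1e-14)
        sse_safe = np.where(perfect | degenerate, 1.0, sse)
        se = np.sqrt(sse_safe / df / np.where(sxx > 0, sxx, 1.0))
        t = np.where(degenerate, 0.0, beta / se)
        t = np.where(perfect, np.copysign(np.inf, beta), t)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, np.maximum(p, MIN_P))
    se = np.where(degenerate, np.nan, np.where(perfect, 0.0, se))
    return {
        "beta": beta, "se": se, "t": t, "p": p, "r": r,
        "n": n, "degenerate": degenerate, "perfect": perfect,
    }


def bulk_pearson(A: np.ndarray, B: np.ndarray) -> dict[str, np.ndarray]:
    """Pearson r and p for every (column of A) x (column of B) pair.

    A fast dense path handles the common complete-data case; any missing
    value routes the affected computation through pairwise complete-case
    sums.  Outputs are (A-columns x B-columns) matrices ``r``, ``p``, ``n``
    and a ``degenerate`` mask (p forced to 1, r to NaN).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValidationError(
            f"row mismatch: A has {A.shape[0]}, B has {B.shape[0]}"
        )
    if np.isfinite(A).all() and np.isfinite(B).all():
        return _bulk_pearson_dense(A, B)
    # pairwise complete-case fallback
    ga, gb = A.shape[1], B.shape[1]
    r = np.empty((ga, gb))
    p = np.empty((ga, gb))
    n = np.empty((ga, gb), dtype=int)
    deg = np.zeros((ga, gb), dtype=bool)
    for j in range(gb):
        res = bulk_slope(A, B[:, j])
        r[:, j] = res["r"]
        p[:, j] = res["p"]
        n[:, j] = res["n"]
        deg[:, j] = res["degenerate"]
    return {"r": r, "p": p, "n": n, "degenerate": deg}


def _bulk_pearson_dense(A: np.ndarray, B: np.ndarray) -> dict[str, np.ndarray]:
    nobs = A.shape[0]
    if nobs < _MIN_N:
        raise InsufficientDataError(f"{nobs} rows; need >= {_MIN_N}")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    sa = np.einsum("ij,ij->j", Ac, Ac)
    sb = np.einsum("ij,ij->j", Bc, Bc)
    floor_a = nobs * (np.finfo(float).eps * np.maximum(1.0, np.abs(A).max(axis=0))) ** 2 * 4.0
    floor_b = nobs * (np.finfo(float).eps * np.maximum(1.0, np.abs(B).max(axis=0))) ** 2 * 4.0
    deg = (sa <= floor_a)[:, None] | (sb <= floor_b)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        cross = Ac.T @ Bc
        r = cross / np.sqrt(np.outer(sa, sb))
        r = np.where(deg, np.nan, np.clip(r, -1.0, 1.0))
        df = nobs - 2
        one_minus = 1.0 - r * r
        t = r * np.sqrt(df / np.where(one_minus > 0, one_minus, np.inf))
        exact = (~deg) & (one_minus <= 1e-14)
        t = np.where(exact, np.copysign(np.inf, r), t)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(deg, 1.0, np.maximum(p, MIN_P))
    n = np.full(r.shape, nobs, dtype=int)
    return {"r": r, "p": p, "n": n, "degenerate": deg}
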