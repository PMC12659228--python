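"""Mining a mutation catalogue into cancer-specific simulation presets.

A catalogue is a table of somatic variant records (sample, cancer type,
variant type, locus, zygosity, HGVS description) in the style of a
COSMIC or TCGA export.  For one cancer type the builder computes:

* variant-type and zygosity proportions, both pooled over every record
  (*all-sample perspective*) and per individual sample (*one-sample
  perspective*);
* empirical distributions of the total number of variants per sample,
  of variant lengths per type (INS, DEL, DUP, and the two components of
  a delins: the deleted span ``DELins`` and the inserted span
  ``delINS``), and of the genomic distances between adjacent variants
  of the same type (per sample, per chromosome, aggregated);
* for each distribution, after dropping values with relative frequency
  below 1%, maximum-likelihood fits to ten families (Weibull,
  lognormal, normal, negative binomial, exponential, logistic, Poisson,
  gamma, geometric, Cauchy), six goodness-of-fit metrics per fit (AIC,
  BIC, KS, AD, CvM, CHISQ) and a majority-vote best family.

SNP lengths are by construction the constant 0 (a SNP is a 1-bp
deletion followed by a 1-bp insertion) and are never fitted; only SNP
inter-variant distances are.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VTYPES",
    "FAMILY_NAMES",
    "HgvsError",
    "DegenerateDistributionError",
    "CatalogueRecord",
    "EmpiricalDistribution",
    "FitResult",
    "Preset",
    "parse_hgvs_lengths",
    "read_catalogue",
    "compute_proportions",
    "compute_distance_distribution",
    "filter_rare",
    "fit_family",
    "gof_metrics",
    "majority_vote",
    "fit_standard_errors",
    "build_preset",
]

VTYPES = ("SNP", "INS", "DEL", "DUP", "DELINS")
ZYGOSITIES = ("het", "hom")
METRICS = ("AIC", "BIC", "KS", "AD", "CvM", "CHISQ")

# The 21 cancer types for which real-database presets are normally built.
CANCER_TYPES = (
    "breast", "lung", "colon", "adrenal gland", "biliary tract", "bone",
    "cervix", "eye", "kidney", "liver", "oesophagus", "ovary", "pancreas",
    "pleura", "prostate", "skin", "soft tissue", "stomach", "testis",
    "thymus", "thyroid",
)


class HgvsError(ValueError):
    """Raised on an HGVS form the length parser does not support."""


class DegenerateDistributionError(ValueError):
    """Raised when an operation would leave a distribution empty."""


# ---------------------------------------------------------------------------
# HGVS length arithmetic
# ---------------------------------------------------------------------------

_HGVS_RE = re.compile(r"^g\.(\d+)(?:_(\d+))?(.*)$")
_SNV_RE = re.compile(r"^([ACGT])>([ACGT])$")
_DELINS_RE = re.compile(r"^del(?:[ACGT]*)ins([ACGT]+|\d+)$")
_DEL_RE = re.compile(r"^del([ACGT]*)$")
_INS_RE = re.compile(r"^ins([ACGT]+|\d+)$")
_DUP_RE = re.compile(r"^dup([ACGT]*)$")


def parse_hgvs_lengths(hgvs: str) -> tuple[int, int]:
    """Derive (del_len, ins_len) from a simple genomic HGVS description.

    Supported forms: ``g.100A>T`` -> (1, 1); ``g.100del``/``g.100_102del``
    -> (span, 0); ``g.100_101insACT`` -> (0, 3); ``g.100_104dup`` -> (0, 5)
    with the duplicated-span length reported as the inserted length;
    ``g.100_102delinsAAAA`` -> (3, 4).
    """
    m = _HGVS_RE.match(hgvs.strip())
    if not m:
        raise HgvsError(f"unsupported HGVS form: {hgvs!r}")
    start = int(m.group(1))
    end = int(m.group(2)) if m.group(2) else start
    if end < start:
        raise HgvsError(f"inverted interval in {hgvs!r}")
    span = end - start + 1
    tail = m.group(3)
    sm = _SNV_RE.match(tail)
    if sm:
        if span != 1:
            raise HgvsError(f"SNV with an interval: {hgvs!r}")
        return (1, 1)
    dm = _DELINS_RE.match(tail)
    if dm:
        arg = dm.group(1)
        ins_len = int(arg) if arg.isdigit() else len(arg)
        return (span, ins_len)
    if _DEL_RE.match(tail):
        return (span, 0)
    im = _INS_RE.match(tail)
    if im:
        arg = im.group(1)
        return (0, int(arg) if arg.isdigit() else len(arg))
    if _DUP_RE.match(tail):
        return (0, span)
    raise HgvsError(f"unsupported HGVS form: {hgvs!r}")


# ---------------------------------------------------------------------------
# Catalogue records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalogueRecord:
    sample_id: str
    cancer_type: str
    vtype: str
    chrom: str
    pos: int
    zygosity: str  # het | hom | unknown
    hgvs: str
    del_len: int = 0
    ins_len: int = 0


CATALOGUE_COLUMNS = ["sample_id", "cancer_type", "vtype", "chrom", "pos", "zygosity", "hgvs"]


def read_catalogue(path: str | Path) -> pd.DataFrame:
    """Read a catalogue TSV and derive event lengths from the HGVS column.

    Records with an unparseable HGVS string are dropped; the number
    skipped is stored in ``df.attrs['n_skipped']``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = [c for c in CATALOGUE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalogue is missing columns: {missing}")
    del_lens, ins_lens, keep = [], [], []
    for hgvs in df["hgvs"]:
        try:
            d, i = parse_hgvs_lengths(str(hgvs))
            del_lens.append(d)
            ins_lens.append(i)
            keep.append(True)
        except HgvsError:
            del_lens.append(0)
            ins_lens.append(0)
            keep.append(False)
    df = df.assign(del_len=del_lens, ins_len=ins_lens)
    n_skipped = int(len(keep) - sum(keep))
    df = df[pd.Series(keep, index=df.index)].reset_index(drop=True)
    df.attrs["n_skipped"] = n_skipped
    return df


# ---------------------------------------------------------------------------
# Empirical distributions
# ---------------------------------------------------------------------------

class EmpiricalDistribution:
    """A value -> count table with sampling and expansion helpers."""

    def __init__(self, counts: dict[int, int] | None = None):
        self.counts: dict[int, int] = {}
        if counts:
            for v, c in counts.items():
                if c < 1:
                    raise ValueError(f"count for value {v} must be >= 1, got {c}")
                self.counts[int(v)] = int(c)

    @classmethod
    def from_values(cls, values: Iterable[int]) -> "EmpiricalDistribution":
        d = cls()
        for v in values:
            d.counts[int(v)] = d.counts.get(int(v), 0) + 1
        return d

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EmpiricalDistribution):
            return NotImplemented
        return self.counts == other.counts

    def expand(self) -> np.ndarray:
        """Sorted sample with every value repeated by its count."""
        if not self.counts:
            return np.array([], dtype=np.int64)
        return np.repeat(
            np.array(sorted(self.counts), dtype=np.int64),
            [self.counts[v] for v in sorted(self.counts)],
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if not self.counts:
            raise DegenerateDistributionError("cannot sample from an empty distribution")
        values = np.array(sorted(self.counts), dtype=np.int64)
        weights = np.array([self.counts[v] for v in sorted(self.counts)], dtype=float)
        return rng.choice(values, size=n, p=weights / weights.sum())


def filter_rare(
    d: EmpiricalDistribution, threshold: float = 0.01
) -> EmpiricalDistribution:
    """Drop values whose relative frequency is strictly below ``threshold``.

    A single pass: frequencies are judged against the pre-filter total,
    and surviving counts are left unchanged.  A value sitting exactly at
    the threshold survives.
    """
    total = d.total
    if total == 0:
        raise DegenerateDistributionError("cannot filter an empty distribution")
    kept = {v: c for v, c in d.counts.items() if c / total >= threshold}
    if not kept:
        raise DegenerateDistributionError(
            "rare-value filter removed every value (all frequencies < threshold)"
        )
    return EmpiricalDistribution(kept)


# ---------------------------------------------------------------------------
# Proportions and distances
# ---------------------------------------------------------------------------

def _props(series: pd.Series, keys: Sequence[str]) -> dict[str, float]:
    counts = series.value_counts()
    total = int(counts.sum())
    return {k: float(counts.get(k, 0)) / total for k in keys}


def compute_proportions(records: pd.DataFrame) -> dict:
    """Type and zygosity proportions, pooled and per sample.

    Zygosity proportions only consider records whose zygosity is known
    (het/hom); they are ``None`` when no record carries zygosity, as in
    TCGA-style catalogues.
    """
    if len(records) == 0:
        raise ValueError("no records to compute proportions from")
    known_zyg = records[records["zygosity"].isin(ZYGOSITIES)]
    all_sample = {
        "type_props": _props(records["vtype"], VTYPES),
        "zyg_props": _props(known_zyg["zygosity"], ZYGOSITIES) if len(known_zyg) else None,
    }
    per_sample = []
    for sample_id, group in records.groupby("sample_id", sort=True):
        kz = group[group["zygosity"].isin(ZYGOSITIES)]
        per_sample.append(
            {
                "sample_id": str(sample_id),
                "n_variants": int(len(group)),
                "type_props": _props(group["vtype"], VTYPES),
                "zyg_props": _props(kz["zygosity"], ZYGOSITIES) if len(kz) else None,
            }
        )
    return {"all_sample": all_sample, "per_sample": per_sample}


def compute_distance_distribution(records: pd.DataFrame) -> EmpiricalDistribution:
    """Distances between adjacent same-chromosome variants.

    Per sample and per chromosome, positions are sorted and successive
    differences taken; distances from all samples are pooled.
    Chromosomes holding fewer than two variants contribute nothing.
    """
    distances: list[int] = []
    for (_, _), group in records.groupby(["sample_id", "chrom"], sort=True):
        pos = np.sort(group["pos"].to_numpy())
        if len(pos) >= 2:
            distances.extend(np.diff(pos).tolist())
    return EmpiricalDistribution.from_values(distances)


# ---------------------------------------------------------------------------
# The ten distribution families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Family:
    name: str
    discrete: bool
    param_names: tuple[str, ...]
    fit: Callable[[np.ndarray], tuple[float, ...]]
    nll: Callable[[tuple[float, ...], np.ndarray], float]
    cdf: Callable[[np.ndarray, tuple[float, ...]], np.ndarray]
    pmf: Callable[[np.ndarray, tuple[float, ...]], np.ndarray] | None
    rvs: Callable[[tuple[float, ...], int, np.random.Generator], np.ndarray]
    support: Callable[[np.ndarray], str | None]  # None = ok, else reason

    @property
    def k(self) -> int:
        return len(self.param_names)


def _sum_nll(logp: np.ndarray) -> float:
    if not np.all(np.isfinite(logp)):
        return math.inf
    return float(-logp.sum())


def _needs_positive(x: np.ndarray) -> str | None:
    return None if np.all(x > 0) else "requires strictly positive values"


def _needs_nonneg_int(x: np.ndarray) -> str | None:
    if not np.all(x == np.floor(x)):
        return "requires integer values"
    return None if np.all(x >= 0) else "requires non-negative values"


def _needs_pos_int(x: np.ndarray) -> str | None:
    if not np.all(x == np.floor(x)):
        return "requires integer values"
    return None if np.all(x >= 1) else "requires values >= 1"


def _spread(x: np.ndarray) -> str | None:
    return None if np.unique(x).size > 1 else "degenerate (constant) sample"


def _both(*checks):
    def run(x: np.ndarray) -> str | None:
        for c in checks:
            reason = c(x)
            if reason:
                return reason
        return None

    return run


def _fit_nbinom(x: np.ndarray) -> tuple[float, float]:
    """Profile MLE for negative binomial (r, p): for fixed r the MLE of
    p is r / (r + mean); r is found by a 1-D search on log r."""
    mean = float(x.mean())

    def nll_logr(logr: float) -> float:
        r = math.exp(logr)
        p = r / (r + mean)
        return _sum_nll(stats.nbinom.logpmf(x, r, p))

    res = optimize.minimize_scalar(nll_logr, bounds=(-8.0, 12.0), method="bounded")
    r = math.exp(float(res.x))
    return (r, r / (r + mean))


def _families() -> dict[str, Family]:
    fams: dict[str, Family] = {}

    def add(fam: Family) -> None:
        fams[fam.name] = fam

    add(Family(
        "weibull", False, ("shape", "scale"),
        fit=lambda x: tuple(np.delete(stats.weibull_min.fit(x, floc=0), 1)),
        nll=lambda p, x: _sum_nll(stats.weibull_min.logpdf(x, p[0], scale=p[1])),
        cdf=lambda x, p: stats.weibull_min.cdf(x, p[0], scale=p[1]),
        pmf=None,
        rvs=lambda p, n, rng: stats.weibull_min.rvs(p[0], scale=p[1], size=n, random_state=rng),
        support=_both(_needs_positive, _spread),
    ))
    add(Family(
        "lognormal", False, ("sdlog", "scale"),
        fit=lambda x: tuple(np.delete(stats.lognorm.fit(x, floc=0), 1)),
        nll=lambda p, x: _sum_nll(stats.lognorm.logpdf(x, p[0], scale=p[1])),
        cdf=lambda x, p: stats.lognorm.cdf(x, p[0], scale=p[1]),
        pmf=None,
        rvs=lambda p, n, rng: stats.lognorm.rvs(p[0], scale=p[1], size=n, random_state=rng),
        support=_both(_needs_positive, _spread),
    ))
    add(Family(
        "normal", False, ("mean", "sd"),
        fit=lambda x: tuple(stats.norm.fit(x)),
        nll=lambda p, x: _sum_nll(stats.norm.logpdf(x, *p)),
        cdf=lambda x, p: stats.norm.cdf(x, *p),
        pmf=None,
        rvs=lambda p, n, rng: stats.norm.rvs(*p, size=n, random_state=rng),
        support=_spread,
    ))
    add(Family(
        "negative_binomial", True, ("size", "prob"),
        fit=_fit_nbinom,
        nll=lambda p, x: _sum_nll(stats.nbinom.logpmf(x, *p)),
        cdf=lambda x, p: stats.nbinom.cdf(x, *p),
        pmf=lambda x, p: stats.nbinom.pmf(x, *p),
        rvs=lambda p, n, rng: stats.nbinom.rvs(*p, size=n, random_state=rng),
        support=_both(_needs_nonneg_int, _spread),
    ))
    add(Family(
        "exponential", False, ("scale",),
        fit=lambda x: (float(x.mean()),),
        nll=lambda p, x: _sum_nll(stats.expon.logpdf(x, scale=p[0])),
        cdf=lambda x, p: stats.expon.cdf(x, scale=p[0]),
        pmf=None,
        rvs=lambda p, n, rng: stats.expon.rvs(scale=p[0], size=n, random_state=rng),
        support=_both(lambda x: None if np.all(x >= 0) and x.mean() > 0
                      else "requires non-negative values with positive mean", _spread),
    ))
    add(Family(
        "logistic", False, ("loc", "scale"),
        fit=lambda x: tuple(stats.logistic.fit(x)),
        nll=lambda p, x: _sum_nll(stats.logistic.logpdf(x, *p)),
        cdf=lambda x, p: stats.logistic.cdf(x, *p),
        pmf=None,
        rvs=lambda p, n, rng: stats.logistic.rvs(*p, size=n, random_state=rng),
        support=_spread,
    ))
    add(Family(
        "poisson", True, ("mu",),
        fit=lambda x: (float(x.mean()),),
        nll=lambda p, x: _sum_nll(stats.poisson.logpmf(x, p[0])),
        cdf=lambda x, p: stats.poisson.cdf(x, p[0]),
        pmf=lambda x, p: stats.poisson.pmf(x, p[0]),
        rvs=lambda p, n, rng: stats.poisson.rvs(p[0], size=n, random_state=rng),
        support=_both(_needs_nonneg_int,
                      lambda x: None if x.mean() > 0 else "requires positive mean"),
    ))
    add(Family(
        "gamma", False, ("shape", "scale"),
        fit=lambda x: tuple(np.delete(stats.gamma.fit(x, floc=0), 1)),
        nll=lambda p, x: _sum_nll(stats.gamma.logpdf(x, p[0], scale=p[1])),
        cdf=lambda x, p: stats.gamma.cdf(x, p[0], scale=p[1]),
        pmf=None,
        rvs=lambda p, n, rng: stats.gamma.rvs(p[0], scale=p[1], size=n, random_state=rng),
        support=_both(_needs_positive, _spread),
    ))
    add(Family(
        "geometric", True, ("prob",),
        fit=lambda x: (1.0 / float(x.mean()),),
        nll=lambda p, x: _sum_nll(stats.geom.logpmf(x, p[0])),
        cdf=lambda x, p: stats.geom.cdf(x, p[0]),
        pmf=lambda x, p: stats.geom.pmf(x, p[0]),
        rvs=lambda p, n, rng: stats.geom.rvs(p[0], size=n, random_state=rng),
        support=_needs_pos_int,
    ))
    add(Family(
        "cauchy", False, ("loc", "scale"),
        fit=lambda x: tuple(stats.cauchy.fit(x)),
        nll=lambda p, x: _sum_nll(stats.cauchy.logpdf(x, *p)),
        cdf=lambda x, p: stats.cauchy.cdf(x, *p),
        pmf=None,
        rvs=lambda p, n, rng: stats.cauchy.rvs(*p, size=n, random_state=rng),
        support=_spread,
    ))
    return fams


FAMILIES: dict[str, Family] = _families()
FAMILY_NAMES: tuple[str, ...] = tuple(FAMILIES)


@dataclass
class FitResult:
    family: str
    params: tuple[float, ...] = ()
    loglik: float = math.nan
    n: int = 0
    metrics: dict[str, float] = field(default_factory=dict)
    fit_ok: bool = False
    fail_reason: str | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FitResult):
            return NotImplemented
        return (
            self.family == other.family
            and self.params == other.params
            and (self.loglik == other.loglik
                 or (math.isnan(self.loglik) and math.isnan(other.loglik)))
            and self.metrics == other.metrics
            and self.fit_ok == other.fit_ok
        )


def fit_family(d: EmpiricalDistribution, family: str) -> FitResult:
    """Maximum-likelihood fit of one family to an empirical table.

    Never raises on content: support violations, degenerate samples and
    non-convergent fits come back as ``fit_ok=False`` with a reason.
    """
    fam = FAMILIES[family]
    x = d.expand().astype(float)
    if x.size == 0:
        return FitResult(family=family, fail_reason="empty distribution")
    reason = fam.support(x)
    if reason:
        return FitResult(family=family, n=x.size, fail_reason=reason)
    try:
        with np.errstate(all="ignore"):
            params = tuple(float(p) for p in fam.fit(x))
            loglik = -fam.nll(params, x)
    except Exception as exc:  # noqa: BLE001 - fit failures are data, not bugs
        return FitResult(family=family, n=x.size, fail_reason=f"fit failed: {exc}")
    if not all(math.isfinite(p) for p in params) or not math.isfinite(loglik):
        return FitResult(
            family=family, params=params, n=x.size,
            fail_reason="non-finite parameters or likelihood",
        )
    return FitResult(family=family, params=params, loglik=loglik, n=x.size, fit_ok=True)


def gof_metrics(d: EmpiricalDistribution, fit: FitResult) -> dict[str, float]:
    """AIC, BIC, KS, AD, CvM and CHISQ for a successful fit.

    The EDF statistics compare the sample's empirical CDF with the
    fitted CDF evaluated at the observed values.  CHISQ uses the
    observed support for discrete families and equiprobable bins with
    expected count >= 5 (tails merged by construction) for continuous
    ones.
    """
    if not fit.fit_ok:
        raise ValueError(f"cannot score a failed fit ({fit.family}: {fit.fail_reason})")
    fam = FAMILIES[fit.family]
    x = np.sort(d.expand().astype(float))
    n = x.size
    k = fam.k
    aic = 2 * k - 2 * fit.loglik
    bic = k * math.log(n) - 2 * fit.loglik
    with np.errstate(all="ignore"):
        F = np.clip(fam.cdf(x, fit.params), 1e-12, 1 - 1e-12)
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    ks = float(max(np.max(hi - F), np.max(F - lo)))
    i = np.arange(1, n + 1)
    ad = float(-n - np.mean((2 * i - 1) * (np.log(F) + np.log(1 - F[::-1]))))
    cvm = float(1.0 / (12 * n) + np.sum((F - (2 * i - 1) / (2 * n)) ** 2))
    if fam.discrete:
        values = np.array(sorted(d.counts), dtype=float)
        observed = np.array([d.counts[int(v)] for v in values], dtype=float)
        with np.errstate(all="ignore"):
            expected = n * fam.pmf(values, fit.params)  # type: ignore[misc]
        mask = expected > 0
        with np.errstate(all="ignore"):
            chisq = float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))
    else:
        m = int(min(max(n // 5, 2), 30))
        with np.errstate(all="ignore"):
            qs = np.linspace(0, 1, m + 1)[1:-1]
            # invert the fitted CDF on the sample range via interpolation-free
            # scipy ppf where available through the frozen cdf
            edges = _ppf(fam, fit.params, qs)
        observed = np.histogram(x, bins=np.concatenate(([-np.inf], edges, [np.inf])))[0]
        expected = np.full(m, n / m)
        chisq = float(np.sum((observed - expected) ** 2 / expected))
    return {"AIC": float(aic), "BIC": float(bic), "KS": ks, "AD": ad,
            "CvM": cvm, "CHISQ": chisq}


_PPF = {
    "weibull": lambda p, q: stats.weibull_min.ppf(q, p[0], scale=p[1]),
    "lognormal": lambda p, q: stats.lognorm.ppf(q, p[0], scale=p[1]),
    "normal": lambda p, q: stats.norm.ppf(q, *p),
    "exponential": lambda p, q: stats.expon.ppf(q, scale=p[0]),
    "logistic": lambda p, q: stats.logistic.ppf(q, *p),
    "gamma": lambda p, q: stats.gamma.ppf(q, p[0], scale=p[1]),
    "cauchy": lambda p, q: stats.cauchy.ppf(q, *p),
}


def _ppf(fam: Family, params: tuple[float, ...], q: np.ndarray) -> np.ndarray:
    return _PPF[fam.name](params, q)


def score_fit(d: EmpiricalDistribution, fit: FitResult) -> FitResult:
    """Attach GOF metrics to a successful fit (no-op on failures)."""
    if fit.fit_ok:
        fit.metrics = gof_metrics(d, fit)
    return fit


def majority_vote(fits: Sequence[FitResult]) -> str:
    """Best family: each of the six metrics votes for its minimizer.

    Ties on vote count are broken by lowest AIC.  Order of the input
    list is irrelevant.
    """
    ok = [f for f in fits if f.fit_ok and f.metrics]
    if not ok:
        raise ValueError("no successful fits to vote over")
    votes: dict[str, int] = {f.family: 0 for f in ok}
    for metric in METRICS:
        winner = min(ok, key=lambda f: (f.metrics[metric], f.family))
        votes[winner.family] += 1
    best_count = max(votes.values())
    contenders = [f for f in ok if votes[f.family] == best_count]
    return min(contenders, key=lambda f: f.metrics["AIC"]).family


def fit_standard_errors(fit: FitResult, d: EmpiricalDistribution) -> tuple[float, ...]:
    """Asymptotic standard errors from the numeric Hessian of the NLL."""
    if not fit.fit_ok:
        raise ValueError("no standard errors for a failed fit")
    fam = FAMILIES[fit.family]
    x = d.expand().astype(float)
    theta = np.array(fit.params, dtype=float)

    def nll(p: np.ndarray) -> float:
        return fam.nll(tuple(p), x)

    kdim = theta.size
    h = np.maximum(1e-4 * np.abs(theta), 1e-6)
    H = np.empty((kdim, kdim))
    f0 = nll(theta)
    for a in range(kdim):
        for b in range(a, kdim):
            if a == b:
                e = np.zeros(kdim); e[a] = h[a]
                H[a, a] = (nll(theta + e) - 2 * f0 + nll(theta - e)) / h[a] ** 2
            else:
                ea = np.zeros(kdim); ea[a] = h[a]
                eb = np.zeros(kdim); eb[b] = h[b]
                H[a, b] = H[b, a] = (
                    nll(theta + ea + eb) - nll(theta + ea - eb)
                    - nll(theta - ea + eb) + nll(theta - ea - eb)
                ) / (4 * h[a] * h[b])
    cov = np.linalg.inv(H)
    return tuple(float(v) for v in np.sqrt(np.maximum(np.diag(cov), 0.0)))


# ---------------------------------------------------------------------------
# Preset assembly
# ---------------------------------------------------------------------------

DISTRIBUTION_KEYS = (
    "total_variants",
    "length_INS", "length_DEL", "length_DUP", "length_delINS", "length_DELins",
    "distance_SNP", "distance_INS", "distance_DEL", "distance_DUP", "distance_DELINS",
)


@dataclass
class FittedDistribution:
    empirical: EmpiricalDistribution
    fits: list[FitResult] = field(default_factory=list)
    best_family: str | None = None
    filtered: bool = True  # False when the 1% filter would have emptied it


@dataclass
class Preset:
    cancer_type: str
    db_tag: str
    type_props_all: dict[str, float]
    zyg_props_all: dict[str, float] | None
    per_sample: list[dict]
    has_zygosity: bool
    distributions: dict[str, FittedDistribution]
    version: int = 1

    # --- JSON round-trip ----------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        def fd_dict(fd: FittedDistribution) -> dict:
            return {
                "empirical": {
                    "values": sorted(fd.empirical.counts),
                    "counts": [fd.empirical.counts[v] for v in sorted(fd.empirical.counts)],
                },
                "fits": [
                    {
                        "family": f.family, "params": list(f.params),
                        "loglik": f.loglik, "n": f.n, "metrics": f.metrics,
                        "fit_ok": f.fit_ok, "fail_reason": f.fail_reason,
                    }
                    for f in fd.fits
                ],
                "best_family": fd.best_family,
                "filtered": fd.filtered,
            }

        payload = {
            "format": "somasim-preset",
            "version": self.version,
            "cancer_type": self.cancer_type,
            "db_tag": self.db_tag,
            "type_props_all": self.type_props_all,
            "zyg_props_all": self.zyg_props_all,
            "per_sample": self.per_sample,
            "has_zygosity": self.has_zygosity,
            "distributions": {k: fd_dict(fd) for k, fd in self.distributions.items()},
        }
        text = json.dumps(payload, indent=1, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Preset":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        if payload.get("format") != "somasim-preset":
            raise ValueError("not a somasim preset file")

        def fd_load(dd: dict) -> FittedDistribution:
            emp = EmpiricalDistribution(
                dict(zip(dd["empirical"]["values"], dd["empirical"]["counts"]))
            )
            fits = [
                FitResult(
                    family=f["family"], params=tuple(f["params"]),
                    loglik=f["loglik"] if f["loglik"] is not None else math.nan,
                    n=f["n"], metrics=f["metrics"], fit_ok=f["fit_ok"],
                    fail_reason=f["fail_reason"],
                )
                for f in dd["fits"]
            ]
            return FittedDistribution(
                empirical=emp, fits=fits, best_family=dd["best_family"],
                filtered=dd["filtered"],
            )

        return cls(
            cancer_type=payload["cancer_type"],
            db_tag=payload["db_tag"],
            type_props_all=payload["type_props_all"],
            zyg_props_all=payload["zyg_props_all"],
            per_sample=payload["per_sample"],
            has_zygosity=payload["has_zygosity"],
            distributions={k: fd_load(dd) for k, dd in payload["distributions"].items()},
            version=payload["version"],
        )


def fit_all_families(d: EmpiricalDistribution) -> FittedDistribution:
    """Filter, fit the ten families, score them and vote."""
    try:
        filtered = filter_rare(d)
        was_filtered = True
    except DegenerateDistributionError:
        filtered = d
        was_filtered = False
    fits = [score_fit(filtered, fit_family(filtered, name)) for name in FAMILY_NAMES]
    try:
        best = majority_vote(fits)
    except ValueError:
        best = None
    return FittedDistribution(
        empirical=filtered, fits=fits, best_family=best, filtered=was_filtered
    )


def _ensure_lengths(df: pd.DataFrame) -> pd.DataFrame:
    """Derive del_len/ins_len from the HGVS column when absent
    (read_catalogue already provides them; in-memory frames may not)."""
    if "del_len" in df.columns and "ins_len" in df.columns:
        return df
    pairs = [parse_hgvs_lengths(str(h)) for h in df["hgvs"]]
    return df.assign(
        del_len=[p[0] for p in pairs], ins_len=[p[1] for p in pairs]
    )


def build_preset(catalogue: pd.DataFrame, cancer_type: str, db_tag: str) -> Preset:
    """Mine one cancer type of a catalogue into a Preset."""
    catalogue = _ensure_lengths(catalogue)
    records = catalogue[catalogue["cancer_type"] == cancer_type]
    if len(records) == 0:
        raise ValueError(f"catalogue has no records for cancer type {cancer_type!r}")
    props = compute_proportions(records)

    def length_dist(vtype: str, column: str) -> EmpiricalDistribution:
        sub = records[records["vtype"] == vtype]
        values = sub[column][sub[column] >= 1]
        return EmpiricalDistribution.from_values(values.tolist())

    raw: dict[str, EmpiricalDistribution] = {
        "total_variants": EmpiricalDistribution.from_values(
            [p["n_variants"] for p in props["per_sample"]]
        ),
        "length_INS": length_dist("INS", "ins_len"),
        "length_DEL": length_dist("DEL", "del_len"),
        "length_DUP": length_dist("DUP", "ins_len"),
        "length_delINS": length_dist("DELINS", "ins_len"),
        "length_DELins": length_dist("DELINS", "del_len"),
    }
    for vtype in VTYPES:
        raw[f"distance_{vtype}"] = compute_distance_distribution(
            records[records["vtype"] == vtype]
        )
    distributions = {
        key: fit_all_families(d) if d.total > 0
        else FittedDistribution(empirical=d, filtered=False)
        for key, d in raw.items()
    }
    return Preset(
        cancer_type=cancer_type,
        db_tag=db_tag,
        type_props_all=props["all_sample"]["type_props"],
        zyg_props_all=props["all_sample"]["zyg_props"],
        per_sample=props["per_sample"],
        has_zygosity=props["all_sample"]["zyg_props"] is not None,
        distributions=distributions,
    )
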