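"""Clonal competition dynamics from longitudinal VAF data.

Fits the replicator model (see :mod:`clonesplice.model`) to ddPCR-style VAF
trajectories of co-resident mutant clones, detects frequency inversions, and
tests colony-genotype counts against the bulk expectation with an exact
binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import (
    DisjointWindowsError,
    InputError,
    NonIdentifiableError,
    UndefinedTestError,
    UnsupportedModelError,
)
from .model import replicator_fractions

__all__ = [
    "VafTimeSeries",
    "CompetitionFit",
    "ColonyEnrichmentResult",
    "vaf_to_cell_fraction",
    "colony_enrichment_test",
    "fit_competition_model",
    "detect_inversion",
]


@dataclass
class VafTimeSeries:
    """Allele-frequency trajectory of one variant over sampling times.

    Times are months post diagnosis; ``censored`` marks observations below
    the ddPCR detection limit (reported as 0%).
    """

    variant_id: str
    times: np.ndarray
    vaf: np.ndarray
    droplets: np.ndarray
    censored: np.ndarray = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.vaf = np.asarray(self.vaf, dtype=float)
        self.droplets = np.asarray(self.droplets, dtype=int)
        if self.censored is None:
            self.censored = np.zeros(self.times.shape, dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        n = len(self.times)
        if not (len(self.vaf) == len(self.droplets) == len(self.censored) == n):
            raise InputError(f"{self.variant_id}: ragged observation arrays")
        if n and np.any(np.diff(self.times) <= 0):
            raise InputError(f"{self.variant_id}: sampling times must be strictly increasing")
        if np.any((self.vaf < 0) | (self.vaf > 1)):
            raise InputError(f"{self.variant_id}: VAF outside [0, 1]")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class CompetitionFit:
    """Result of fitting the replicator model to a set of VAF trajectories."""

    variants: tuple
    selection_coeffs: np.ndarray          # per year, relative to WT
    selection_stderr: np.ndarray          # bootstrap SE (nan if n_boot = 0)
    initial_fractions: np.ndarray         # cell fractions at the first time point
    residual: float                       # root-mean-square VAF residual
    n_boot: int = 0

    def predict_vaf(self, variant_id: str, times_months) -> np.ndarray:
        """Model VAF trajectory for one fitted clone at the given months."""
        i = self.variants.index(variant_id)
        t_years = np.asarray(times_months, dtype=float) / 12.0
        frac = replicator_fractions(self.selection_coeffs, self.initial_fractions, t_years)
        return frac[:, i] / 2.0


@dataclass
class ColonyEnrichmentResult:
    """Exact binomial test of clone counts among single-cell-derived colonies."""

    k_clone: int
    n_total: int
    expected_fraction: float
    p_value: float
    alternative: str
    compartment: str | None = None


def vaf_to_cell_fraction(vaf: float, zygosity: str = "heterozygous", copy_number: int = 2) -> float:
    """Convert a variant allele frequency to a mutant-cell fraction.

    Only the heterozygous diploid model is supported, where every mutant
    cell contributes one mutant of two alleles: fraction = min(1, 2*vaf).
    """
    if zygosity != "heterozygous" or copy_number != 2:
        raise UnsupportedModelError(
            f"unsupported model: zygosity={zygosity!r}, copy_number={copy_number}"
        )
    if not 0.0 <= vaf <= 1.0:
        raise InputError(f"VAF {vaf} outside [0, 1]")
    return min(1.0, 2.0 * vaf)


def colony_enrichment_test(
    k: int,
    n: int,
    expected_fraction: float,
    alternative: str = "two-sided",
    compartment: str | None = None,
) -> ColonyEnrichmentResult:
    """Exact binomial test of k clone colonies out of n against a null fraction.

    The null fraction is typically twice the contemporaneous bulk VAF
    (heterozygous diploid).  ``two-sided`` is 2 x min(lower tail, upper
    tail) capped at 1.
    """
    if n <= 0:
        raise UndefinedTestError("colony enrichment test undefined for n = 0")
    if not 0 <= k <= n:
        raise InputError(f"k={k} outside [0, n={n}]")
    if not 0.0 <= expected_fraction <= 1.0:
        raise InputError(f"expected_fraction {expected_fraction} outside [0, 1]")
    p_greater = float(stats.binom.sf(k - 1, n, expected_fraction))
    p_less = float(stats.binom.cdf(k, n, expected_fraction))
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise InputError(f"unknown alternative {alternative!r}")
    return ColonyEnrichmentResult(
        k_clone=int(k),
        n_total=int(n),
        expected_fraction=float(expected_fraction),
        p_value=p,
        alternative=alternative,
        compartment=compartment,
    )


def _pack_initial(series, detection_limit):
    """Starting point: s from endpoint log-ratios, f0 from first VAFs."""
    f0 = np.array([min(0.95, max(1e-4, 2.0 * s.vaf[0])) for s in series])
    if f0.sum() >= 0.98:
        f0 *= 0.98 / f0.sum()
    s0 = []
    for s in series:
        v0 = max(s.vaf[0], detection_limit)
        v1 = max(s.vaf[-1], detection_limit)
        dt = max((s.times[-1] - s.times[0]) / 12.0, 1e-6)
        s0.append(np.clip(np.log(v1 / v0) / dt, -2.0, 2.0))
    f_wt0 = max(1e-4, 1.0 - f0.sum())
    return np.concatenate([s0, np.log(f0 / f_wt0)])


def _unpack(x, k):
    s = x[:k]
    a = x[k:]
    # multinomial-logit with WT as the baseline keeps fractions in the simplex
    e = np.exp(a - max(a.max(), 0.0))
    f0 = e / (np.exp(-max(a.max(), 0.0)) + e.sum())
    return s, f0


def fit_competition_model(
    series,
    detection_limit: float = 0.001,
    n_boot: int = 200,
    seed: int = 0,
) -> CompetitionFit:
    """Least-squares fit of the replicator model to observed VAF trajectories.

    One selection coefficient and one initial fraction per clone are
    estimated jointly (WT fixed at s = 0).  Censored observations (VAF
    reported below ``detection_limit``) contribute a one-sided residual:
    they penalise predictions above the limit only.  Standard errors come
    from a seeded parametric bootstrap resampling droplet counts.
    """
    series = list(series)
    if not series:
        raise InputError("no VAF series supplied")
    for s in series:
        if len(s) < 2:
            raise NonIdentifiableError(
                f"{s.variant_id}: a single time point cannot identify a selection coefficient"
            )
    if sum(len(s) for s in series) < 3:
        raise NonIdentifiableError("need at least 3 time points overall")
    k = len(series)

    def residuals(x):
        s_coef, f0 = _unpack(x, k)
        out = []
        for i, ser in enumerate(series):
            pred = replicator_fractions(s_coef, f0, ser.times / 12.0)[:, i] / 2.0
            r = pred - ser.vaf
            r[ser.censored] = np.maximum(0.0, pred[ser.censored] - detection_limit)
            out.append(r)
        return np.concatenate(out)

    x0 = _pack_initial(series, detection_limit)
    sol = optimize.least_squares(residuals, x0, method="trf", xtol=1e-12, ftol=1e-12)
    s_hat, f0_hat = _unpack(sol.x, k)
    rms = float(np.sqrt(np.mean(sol.fun**2)))

    stderr = np.full(k, np.nan)
    if n_boot > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
        boots = np.empty((n_boot, k))
        for b in range(n_boot):
            resampled = []
            for i, ser in enumerate(series):
                pred = replicator_fractions(s_hat, f0_hat, ser.times / 12.0)[:, i] / 2.0
                counts = rng.binomial(ser.droplets, np.clip(pred, 0.0, 1.0))
                vaf = counts / ser.droplets
                resampled.append(
                    VafTimeSeries(ser.variant_id, ser.times, vaf, ser.droplets,
                                  vaf < detection_limit)
                )
            bfit = fit_competition_model(resampled, detection_limit, n_boot=0)
            boots[b] = bfit.selection_coeffs
        stderr = boots.std(axis=0, ddof=1)

    return CompetitionFit(
        variants=tuple(s.variant_id for s in series),
        selection_coeffs=s_hat,
        selection_stderr=stderr,
        initial_fractions=f0_hat,
        residual=rms,
        n_boot=n_boot,
    )


def detect_inversion(series_a: VafTimeSeries, series_b: VafTimeSeries):
    """Earliest time (months) at which two linearly interpolated VAF
    trajectories cross, or ``None`` if they never do.

    Identical trajectories return the earliest shared time (the whole
    window is a tie; the documented rule is to report its start).
    """
    t0 = max(series_a.times[0], series_b.times[0])
    t1 = min(series_a.times[-1], series_b.times[-1])
    if t0 > t1:
        raise DisjointWindowsError(
            f"observation windows of {series_a.variant_id} and {series_b.variant_id} do not overlap"
        )
    grid = np.unique(np.concatenate([
        series_a.times[(series_a.times >= t0) & (series_a.times <= t1)],
        series_b.times[(series_b.times >= t0) & (series_b.times <= t1)],
        [t0, t1],
    ]))
    va = np.interp(grid, series_a.times, series_a.vaf)
    vb = np.interp(grid, series_b.times, series_b.vaf)
    d = va - vb
    if np.all(d == 0):
        return float(grid[0])
    for i in range(len(grid)):
        if d[i] == 0:
            return float(grid[i])
        if i + 1 < len(grid) and d[i] * d[i + 1] < 0:
            frac = d[i] / (d[i] - d[i + 1])
            return float(grid[i] + frac * (grid[i + 1] - grid[i]))
    return None
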