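"""Elasticity spectra and the nanomechanical fingerprint (LEP/HEP decomposition).

A specimen's spectrum pools the QC-passing moduli of its 10-15 force maps.
Because moduli are positive and right-skewed the spectrum lives on log10(E):
histogram (Freedman-Diaconis bins), kernel-density estimate (Silverman
bandwidth), and a 1- or 2-component Gaussian mixture selected by BIC.  The
lower-mean component is the lower elasticity peak (LEP, soft cells), the
higher-mean one the higher elasticity peak (HEP, collagen); "peak" positions
are the back-transformed component means in kPa.  Heterogeneity is summarized
by the coefficient of variation and interquartile range on the linear scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

from .forcecurves import ElasticityMap
from .stats import rout_outliers, median_center

__all__ = [
    "ElasticitySpectrum",
    "NMFSummary",
    "SpectrumComparison",
    "pool_specimen",
    "decompose_peaks",
    "heterogeneity_metrics",
    "compare_spectra",
]


@dataclass
class ElasticitySpectrum:
    """Pooled post-QC moduli of one specimen with log-domain density summaries."""

    values_kpa: np.ndarray
    hist_edges: np.ndarray       # log10(kPa)
    hist_density: np.ndarray
    kde_grid: np.ndarray         # log10(kPa)
    kde_density: np.ndarray
    kde_bandwidth: float
    specimen_id: str = ""
    n_maps: int = 0
    rout_applied: bool = False
    n_outliers_removed: int = 0

    @property
    def n(self) -> int:
        return int(self.values_kpa.size)

    @property
    def log10_values(self) -> np.ndarray:
        return np.log10(self.values_kpa)


@dataclass
class NMFSummary:
    """Nanomechanical fingerprint of one specimen."""

    n_components: int
    lep_mode: float
    hep_mode: float | None
    lep_weight: float
    hep_weight: float
    lep_log_sd: float
    hep_log_sd: float | None
    median_e: float
    cv_percent: float
    iqr: float
    bic_1: float
    bic_2: float
    n: int
    specimen_id: str = ""
    em_fallback: bool = False


@dataclass
class SpectrumComparison:
    u_statistic: float
    p_value: float
    median_shift: float
    hep_mode_difference: float | None
    n_a: int
    n_b: int


class EmptySpectrumError(ValueError):
    """All pixels rejected: no moduli to pool."""


def pool_specimen(
    maps: list[ElasticityMap],
    specimen_id: str = "",
    rout_q: float | None = None,
    kde_points: int = 256,
) -> ElasticitySpectrum:
    """Pool QC-passing moduli across a specimen's maps into a spectrum.

    Pooling is a multiset union, hence order-invariant.  When ``rout_q`` is
    given, robust outlier removal at that FDR level is applied to the pooled
    values before density estimation (the default order of operations).
    """
    if not maps:
        raise ValueError("need at least one elasticity map")
    values = np.concatenate([m.passing_values() for m in maps])
    values = values[np.isfinite(values) & (values > 0)]
    if values.size == 0:
        raise EmptySpectrumError(f"specimen {specimen_id!r}: no moduli passed QC")

    n_removed = 0
    rout_applied = False
    if rout_q is not None and values.size >= 10:
        res = rout_outliers(values, q=rout_q)
        n_removed = int(len(res.outlier_indices))
        values = values[res.inlier_mask]
        rout_applied = True

    logv = np.log10(values)
    iqr = np.subtract(*np.percentile(logv, [75, 25]))
    if values.size > 1 and iqr > 0:
        bin_width = 2.0 * iqr / values.size ** (1.0 / 3.0)
        n_bins = max(1, int(np.ceil((logv.max() - logv.min()) / bin_width)))
    else:
        n_bins = 1
    hist_density, hist_edges = np.histogram(logv, bins=n_bins, density=True)

    if values.size > 1 and np.ptp(logv) > 0:
        kde = sps.gaussian_kde(logv, bw_method="silverman")
        pad = 3.0 * kde.factor * logv.std(ddof=1)
        grid = np.linspace(logv.min() - pad, logv.max() + pad, kde_points)
        density = kde(grid)
        bandwidth = float(kde.factor * logv.std(ddof=1))
    else:
        grid = np.array([logv[0] - 0.5, logv[0], logv[0] + 0.5])
        density = np.array([0.0, 1.0, 0.0])
        bandwidth = 0.0

    return ElasticitySpectrum(
        values_kpa=values,
        hist_edges=hist_edges,
        hist_density=hist_density,
        kde_grid=grid,
        kde_density=density,
        kde_bandwidth=bandwidth,
        specimen_id=specimen_id,
        n_maps=len(maps),
        rout_applied=rout_applied,
        n_outliers_removed=n_removed,
    )


def heterogeneity_metrics(values_kpa: np.ndarray) -> dict[str, float]:
    """CV% (sample sd / mean on the linear kPa scale), IQR, quartiles, median."""
    v = np.asarray(values_kpa, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "cv_percent": float(100.0 * v.std(ddof=1) / v.mean()),
        "iqr": float(q3 - q1),
        "q1": float(q1),
        "q3": float(q3),
        "median": float(med),
    }


def decompose_peaks(
    spectrum: ElasticitySpectrum,
    n_init: int = 5,
    random_state: int = 0,
    min_n: int = 50,
) -> NMFSummary:
    """Fit 1- and 2-component Gaussian mixtures on log10(E), select by BIC.

    Components are labeled by mean (lower -> LEP, higher -> HEP) so the result
    is invariant to EM's internal ordering; modes are back-transformed to kPa.
    On EM failure the single-component fallback is returned with a flag.
    """
    if spectrum.n < min_n:
        raise ValueError(f"need >= {min_n} pooled moduli, got {spectrum.n}")
    x = spectrum.log10_values.reshape(-1, 1)

    fits = {}
    fallback = False
    for k in (1, 2):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm = GaussianMixture(
                    n_components=k, n_init=n_init, random_state=random_state,
                    covariance_type="full",
                ).fit(x)
            if not gm.converged_:
                raise RuntimeError("EM not converged")
            fits[k] = (gm, float(gm.bic(x)))
        except Exception:
            if k == 1:
                raise
            fallback = True
    bic_1 = fits[1][1]
    bic_2 = fits[2][1] if 2 in fits else float("inf")
    k_best = 1 if (fallback or bic_1 <= bic_2) else 2
    gm = fits[k_best][0]

    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(-1))
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]

    het = heterogeneity_metrics(spectrum.values_kpa)
    if k_best == 1:
        return NMFSummary(
            n_components=1,
            lep_mode=float(10.0 ** means[0]),
            hep_mode=None,
            lep_weight=1.0,
            hep_weight=0.0,
            lep_log_sd=float(sds[0]),
            hep_log_sd=None,
            median_e=het["median"],
            cv_percent=het["cv_percent"],
            iqr=het["iqr"],
            bic_1=bic_1,
            bic_2=bic_2,
            n=spectrum.n,
            specimen_id=spectrum.specimen_id,
            em_fallback=fallback,
        )
    return NMFSummary(
        n_components=2,
        lep_mode=float(10.0 ** means[0]),
        hep_mode=float(10.0 ** means[1]),
        lep_weight=float(weights[0]),
        hep_weight=float(weights[1]),
        lep_log_sd=float(sds[0]),
        hep_log_sd=float(sds[1]),
        median_e=het["median"],
        cv_percent=het["cv_percent"],
        iqr=het["iqr"],
        bic_1=bic_1,
        bic_2=bic_2,
        n=spectrum.n,
        specimen_id=spectrum.specimen_id,
        em_fallback=False,
    )


def compare_spectra(
    spec_a: ElasticitySpectrum,
    spec_b: ElasticitySpectrum,
    normalize: str | None = "reference_mean",
    summaries: tuple[NMFSummary, NMFSummary] | None = None,
) -> SpectrumComparison:
    """Mann-Whitney U comparison of two normalized spectra.

    ``reference_mean`` (default) expresses both pooled samples as fold of the
    second spectrum's mean — a common scale, so the rank test retains its
    sensitivity to stochastic ordering.  ``median`` centers each sample by its
    own median instead; note that per-sample centering equalizes the medians
    by construction and leaves the rank test sensitive to shape only.
    """
    a = spec_a.values_kpa
    b = spec_b.values_kpa
    if a.size == 0 or b.size == 0:
        raise ValueError("both spectra must be non-empty")
    if normalize == "reference_mean":
        ref = float(b.mean())
        a = a / ref
        b = b / ref
    elif normalize == "median":
        a = median_center(a)
        b = median_center(b)
    elif normalize is not None:
        raise ValueError(f"unknown normalization {normalize!r}")
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    hep_diff = None
    if summaries is not None:
        sa, sb = summaries
        if sa.hep_mode is not None and sb.hep_mode is not None:
            hep_diff = sa.hep_mode - sb.hep_mode
    return SpectrumComparison(
        u_statistic=float(u),
        p_value=float(p),
        median_shift=float(np.median(spec_a.values_kpa) - np.median(spec_b.values_kpa)),
        hep_mode_difference=hep_diff,
        n_a=int(a.size),
        n_b=int(b.size),
    )
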