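"""The three computational experiments of the tACS modelling pipeline.

1. Single-node entrainment sweeps over stimulation frequency (4-18 Hz) and
   intensity (0-200 pA) for the prototypical amplitude distributions,
   yielding Arnold-tongue maps of the peak-to-stimulation frequency ratio.
2. Cohort intensity calibration: grid search over the global scaling constant
   V against a target group-mean alpha-power rise in a designated cluster of
   regions.
3. Statistics of stimulation efficacy: per-subject Wilcoxon signed-rank
   comparisons with Holm step-down correction, and stepwise robust multiple
   linear regression (iteratively reweighted least squares with Huber
   weighting) of the per-region alpha rise on field-distribution, structural
   and functional predictors.

Intensity convention for single-node sweeps: amplitude samples are
dimensionless factors; V is set per assignment so that the maximum injected
amplitude max|A_i * V| equals the grid intensity in pA, mapping each
distribution onto the 0-200 pA sweep axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

from . import fixtures as fx
from .efield import (
    NormalComponentDistribution,
    group_by_region,
    project_normal,
    summarize,
)
from .engine import SimulationResult, StimulusSpec, assign_stimulus, simulate
from .metrics import ALPHA_BAND, band_power, iaf, psd
from .network import NetworkModel, build_network, build_population

__all__ = [
    "SweepResult",
    "CalibrationResult",
    "RegressionTable",
    "MLRResult",
    "Subject",
    "DegenerateBaselineError",
    "CollinearityError",
    "single_node_sweep",
    "classify_sync_state",
    "alpha_rise",
    "calibrate_intensity",
    "make_synthetic_cohort",
    "build_regression_table",
    "robust_mlr",
    "lowered_subset_mlr",
    "wilcoxon_holm",
    "holm_step_down",
    "natural_frequency",
]

SWEEP_FREQS_HZ = np.arange(4.0, 18.01, 1.0)
SWEEP_INTENSITIES_PA = np.arange(0.0, 200.01, 25.0)
HUBER_T = 1.345
IRLS_TOL = 1e-8
IRLS_MAXITER = 50


class DegenerateBaselineError(ValueError):
    """Baseline band power is zero; a relative rise is undefined."""


class CollinearityError(ValueError):
    def __init__(self, columns):
        super().__init__(f"rank-deficient design; offending columns: {columns}")
        self.columns = list(columns)


def _child_seed(*keys) -> int:
    import zlib

    ints = [k if isinstance(k, (int, np.integer)) else zlib.crc32(str(k).encode())
            for k in keys]
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# single-node sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Grid of spectral read-outs of a stimulated single node.

    All per-cell arrays have shape (n_freqs, n_intensities); frequency
    read-outs are medians over repetitions, band powers means.  ``ratio`` is
    the peak-to-stimulation frequency ratio,
    the quantity whose plateaus at 1 and 2 delineate the 1:1 and 2:1
    synchronization tongues.
    """

    freqs: np.ndarray
    intensities: np.ndarray
    peak_freq: np.ndarray
    ratio: np.ndarray
    power_peak: np.ndarray
    power_stim: np.ndarray
    reps: int
    seed: int
    natural_freq: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.freqs):
            for j, amp in enumerate(self.intensities):
                rows.append(
                    dict(freq_hz=f, intensity_pa=amp,
                         peak_freq=self.peak_freq[i, j], ratio=self.ratio[i, j],
                         power_peak=self.power_peak[i, j],
                         power_stim=self.power_stim[i, j])
                )
        return pd.DataFrame(rows)


def natural_frequency(
    model: NetworkModel | None = None,
    duration_s: float = 12.0,
    seeds=(0, 1, 2),
) -> float:
    """Median unstimulated LFP peak frequency of a node over seeds."""
    model = model or build_population()
    peaks = [
        psd(simulate(model, None, duration_s, seed=s).lfp[0], 0.1).peak_freq
        for s in seeds
    ]
    return float(np.median(peaks))


def single_node_sweep(
    dist,
    freqs: np.ndarray = SWEEP_FREQS_HZ,
    intensities: np.ndarray = SWEEP_INTENSITIES_PA,
    reps: int = 3,
    seed: int = 0,
    duration_s: float = 12.0,
    model: NetworkModel | None = None,
) -> SweepResult:
    """Stimulate a single node over a (frequency, intensity) grid.

    ``dist`` is an amplitude sample set (or NormalComponentDistribution).
    Per cell and repetition, per-neuron amplitudes are drawn i.i.d. from the
    distribution and rescaled so the maximum injected amplitude equals the
    cell's intensity; intensity 0 runs are unstimulated baselines.
    """
    samples = dist.samples if isinstance(dist, NormalComponentDistribution) else np.asarray(dist, float)
    model = model or build_population()
    freqs = np.asarray(freqs, float)
    intensities = np.asarray(intensities, float)
    shape = (len(freqs), len(intensities))
    peak = np.zeros(shape)
    ratio = np.zeros(shape)
    p_peak = np.zeros(shape)
    p_stim = np.zeros(shape)
    f_nat = natural_frequency(model, duration_s=duration_s, seeds=(seed % 1000, seed % 1000 + 1))

    for i, f in enumerate(freqs):
        for j, amp in enumerate(intensities):
            pk, rt, pp, ps = [], [], [], []
            for r in range(reps):
                s = _child_seed(seed, i, j, r)
                if amp == 0:
                    stim = None
                else:
                    stim = assign_stimulus(samples, 1.0, f, seed=s, n_neurons=model.n_neurons)
                    peak_a = np.abs(stim.amplitudes).max()
                    stim = replace(stim, V=amp / peak_a)
                res = simulate(model, stim, duration_s, seed=s)
                spec = psd(res.lfp[0], res.dt_ms)
                pk.append(spec.peak_freq)
                rt.append(spec.peak_freq / f)
                pp.append(band_power(spec, spec.peak_freq, 0.5))
                ps.append(band_power(spec, f, 0.5))
            # median over repetitions: the dominant-frequency read-out is a
            # discrete state label, and a single run whose PSD argmax lands
            # on a harmonic would corrupt a mean
            peak[i, j] = np.median(pk)
            ratio[i, j] = np.median(rt)
            p_peak[i, j] = np.mean(pp)
            p_stim[i, j] = np.mean(ps)
    return SweepResult(freqs, intensities, peak, ratio, p_peak, p_stim, reps, seed, f_nat)


def classify_sync_state(ratio: float, tol: float = 0.05) -> str:
    """Deterministic labelling of the entrainment regime from the
    peak-to-stimulation frequency ratio."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if abs(ratio - 1.0) <= tol:
        return "one-to-one"
    if abs(ratio - 2.0) <= 2 * tol:
        return "two-to-one"
    if 1.0 + tol < ratio < 2.0 - 2 * tol:
        return "faster"
    if ratio < 1.0 - tol:
        return "slower"
    return "unlocked"


# ---------------------------------------------------------------------------
# alpha rise and cohort calibration
# ---------------------------------------------------------------------------

def alpha_rise(
    baseline: SimulationResult,
    stim: SimulationResult,
    cluster=None,
    halfwidth_hz: float = 0.5,
    iaf_hz: float | None = None,
) -> float:
    """Percent change of cluster-mean alpha-band power under stimulation.

    The absolute (unnormalized) LFP power of every cluster region is
    integrated over the trial-specific IAF +/- ``halfwidth_hz`` — one IAF
    per trial (the median of the cluster regions' baseline alpha peaks, or
    ``iaf_hz`` if given, e.g. the frequency the trial was stimulated at).
    The rise is ``100 * (P_stim - P_base) / P_base`` with P the mean over
    the cluster regions (all regions by default).
    """
    if baseline.lfp.shape != stim.lfp.shape:
        raise ValueError("baseline and stimulated runs must have the same layout")
    regions = list(baseline.region_ids)
    idx = range(len(regions)) if cluster is None else [regions.index(c) for c in cluster]
    specs_b = {k: psd(baseline.lfp[k], baseline.dt_ms) for k in idx}
    if iaf_hz is None:
        iaf_hz = cluster_iaf(baseline, idx)
    p_base, p_stim = [], []
    for k in idx:
        spec_s = psd(stim.lfp[k], stim.dt_ms)
        p_base.append(band_power(specs_b[k], iaf_hz, halfwidth_hz, normalized=False))
        p_stim.append(band_power(spec_s, iaf_hz, halfwidth_hz, normalized=False))
    pb, ps = float(np.mean(p_base)), float(np.mean(p_stim))
    if pb == 0:
        raise DegenerateBaselineError("zero baseline alpha power in cluster")
    return 100.0 * (ps - pb) / pb


def cluster_iaf(result: SimulationResult, region_indices) -> float:
    """Trial-specific IAF: alpha-band argmax of the cluster-averaged raw
    baseline spectrum (one value per trial, taken where the cluster actually
    carries power — the analogue of reading the IAF off sensor-averaged
    spectra)."""
    specs = [psd(result.lfp[k], result.dt_ms) for k in region_indices]
    freqs = specs[0].freqs
    mean_raw = np.mean([s.raw_power for s in specs], axis=0)
    mask = (freqs >= ALPHA_BAND[0]) & (freqs <= ALPHA_BAND[1])
    return float(freqs[mask][np.argmax(mean_raw[mask])])


@dataclass
class Subject:
    """One synthetic subject: a wired network plus per-region amplitude
    distributions derived from its cortical-sheet field projection."""

    name: str
    model: NetworkModel
    distributions: list  # NormalComponentDistribution per region, model order


@dataclass
class CalibrationResult:
    V_grid: np.ndarray
    rises: np.ndarray  # (n_V, n_subjects, reps) percent
    V_star: float
    target_rise: float

    @property
    def group_mean(self) -> np.ndarray:
        return self.rises.reshape(len(self.V_grid), -1).mean(axis=1)

    @property
    def achieved_rise(self) -> float:
        k = int(np.argmin(np.abs(self.group_mean - self.target_rise)))
        return float(self.group_mean[k])


def make_synthetic_cohort(
    n_subjects: int = 4,
    n_regions: int = 6,
    seed: int = 0,
    coupling: float = 0.0,
    field_magnitude: float = 0.2,
    mesh_resolution: int = 48,
) -> list[Subject]:
    """Generate a cohort of synthetic subjects.

    Each subject gets a log-normal-weight connectome, and a gyrified sheet
    mesh whose folding depth varies across subjects (so per-region normal
    component distributions range from unimodal-shifted on flat parcels to
    bimodal on strongly folded ones), projected against a uniform in-plane
    field along the folding axis.
    """
    cohort = []
    for s in range(n_subjects):
        sub_seed = _child_seed(seed, s)
        conn = fx.make_connectome(n_regions, density=1.0, seed=sub_seed)
        # 1.5-3 mm of folding across the cohort: shallow subjects respond to
        # the tilted field, the most folded ones respond weakly or not at
        # all, giving the responder / non-responder spread of a realistic
        # sample without the extreme frequency-doubling suppression that
        # fully anti-phase (deeply folded) parcels produce
        fold_depth = 1.5 + 1.5 * s / max(n_subjects - 1, 1)
        mesh = fx.make_gyrified_mesh(
            n_gyri=4, fold_depth=fold_depth, sheet_size=60.0,
            resolution=mesh_resolution, region_splits=n_regions, seed=sub_seed,
        )
        # field along the folding axis, tilted toward the white side so flat
        # parcels receive a clearly shifted (orthodromic-biased) distribution
        fieldmap = fx.make_uniform_field(mesh, (1.0, 0.0, -0.5), field_magnitude)
        comps = project_normal(fieldmap, mesh)
        dists = [summarize(d) for d in group_by_region(comps, mesh)]
        model = build_network(conn, coupling=coupling)
        cohort.append(Subject(name=f"S{s}", model=model, distributions=dists))
    return cohort


def _stimulate_subject(
    subject: Subject, V: float, f: float, seed: int
) -> StimulusSpec:
    """Per-neuron amplitudes for a whole network: each region's neurons draw
    from that region's distribution."""
    n_per = subject.model.n_per_region
    amps = np.concatenate([
        assign_stimulus(d, 1.0, f, seed=_child_seed(seed, k), n_neurons=n_per).amplitudes
        for k, d in enumerate(subject.distributions)
    ])
    return StimulusSpec(frequency_hz=f, V=V, amplitudes=amps, seed=seed)


def _cluster_band_power(result: SimulationResult, idx, iaf_hz: float,
                        halfwidth_hz: float) -> float:
    """Cluster-mean absolute band power at the trial IAF."""
    vals = [
        band_power(psd(result.lfp[k], result.dt_ms), iaf_hz, halfwidth_hz,
                   normalized=False)
        for k in idx
    ]
    return float(np.mean(vals))


def calibrate_intensity(
    cohort: list[Subject],
    target_rise: float,
    V_grid: np.ndarray,
    reps: int = 1,
    seed: int = 0,
    duration_s: float = 12.0,
    baseline_duration_s: float | None = None,
    cluster=None,
) -> CalibrationResult:
    """Grid-search the scaling constant V for a target group-mean alpha rise.

    One baseline run per subject fixes the trial-specific IAF (alpha argmax
    of the cluster-mean spectrum) and the baseline cluster band power; the
    baseline may be longer than the stimulated runs
    (``baseline_duration_s``), which sharpens both estimates and so the rise
    denominators.  Each (V, repetition) then drives every neuron at that IAF
    with region-specific amplitudes scaled by V.  V* minimizes the absolute
    difference between the group-mean cluster rise and the target.
    """
    if not cohort or len(V_grid) == 0:
        raise ValueError("cohort and V grid must be non-empty")
    V_grid = np.asarray(V_grid, float)
    base_dur = baseline_duration_s or duration_s
    rises = np.zeros((len(V_grid), len(cohort), reps))
    for si, sub in enumerate(cohort):
        base = simulate(sub.model, None, base_dur, seed=_child_seed(seed, si))
        regions = list(base.region_ids)
        idx = list(range(len(regions))) if cluster is None else [regions.index(c) for c in cluster]
        f_stim = cluster_iaf(base, idx)
        p_base = _cluster_band_power(base, idx, f_stim, 0.5)
        if p_base == 0:
            raise DegenerateBaselineError(f"zero baseline alpha power for {sub.name}")
        for r in range(reps):
            run_seed = _child_seed(seed, si, r)
            for vi, V in enumerate(V_grid):
                if V == 0:
                    rises[vi, si, r] = 0.0
                    continue
                stim = _stimulate_subject(sub, V, f_stim, run_seed)
                res = simulate(sub.model, stim, duration_s, seed=run_seed)
                p_stim = _cluster_band_power(res, idx, f_stim, 0.5)
                rises[vi, si, r] = 100.0 * (p_stim - p_base) / p_base
    group = rises.reshape(len(V_grid), -1).mean(axis=1)
    V_star = float(V_grid[int(np.argmin(np.abs(group - target_rise)))])
    return CalibrationResult(V_grid, rises, V_star, target_rise)


# ---------------------------------------------------------------------------
# regression of stimulation efficacy
# ---------------------------------------------------------------------------

PREDICTORS = [
    "squared_mean",
    "skewness",
    "kurtosis",
    "n_modes",
    "log2_strength",
    "baseline_plv",
    "freq_mismatch",
]


@dataclass
class RegressionTable:
    """One row per (subject, region): standardized predictors of the
    per-region percent alpha-power change."""

    data: pd.DataFrame  # columns: subject, region, response, PREDICTORS

    def __post_init__(self) -> None:
        missing = [c for c in ["response", *PREDICTORS] if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if self.data[["response", *PREDICTORS]].isna().any().any():
            raise ValueError("regression table must have no missing cells")


def standardize(df: pd.DataFrame, columns=PREDICTORS) -> pd.DataFrame:
    out = df.copy()
    for c in columns:
        sd = out[c].std(ddof=0)
        out[c] = (out[c] - out[c].mean()) / sd if sd > 0 else 0.0
    return out


def build_regression_table(
    cohort: list[Subject],
    rises: dict,
    baseline_fc: dict,
    baseline_peaks: dict,
    stim_freqs: dict,
) -> RegressionTable:
    """Assemble the per-(subject, region) predictor table.

    ``rises[name]`` maps to per-region percent alpha change arrays;
    ``baseline_fc[name]`` to the subject's simulated PLV matrix;
    ``baseline_peaks[name]`` to per-region baseline peak frequencies;
    ``stim_freqs[name]`` to the subject's stimulation frequency.
    Predictor columns are standardized to mean 0, unit variance.
    """
    rows = []
    for sub in cohort:
        fc = np.asarray(baseline_fc[sub.name], float)
        np.fill_diagonal(fc := fc.copy(), np.nan)
        strength = sub.model.inter_g.sum(axis=1)
        # guard the log for isolated regions
        strength = np.where(strength > 0, strength, np.nanmin(strength[strength > 0]) / 2
                            if np.any(strength > 0) else 1.0)
        for k, d in enumerate(sub.distributions):
            rows.append(dict(
                subject=sub.name,
                region=d.region,
                response=rises[sub.name][k],
                squared_mean=d.squared_mean,
                skewness=d.skewness,
                kurtosis=d.kurtosis,
                n_modes=d.n_modes,
                log2_strength=np.log2(strength[k]),
                baseline_plv=np.nanmean(fc[k]),
                freq_mismatch=stim_freqs[sub.name] - baseline_peaks[sub.name][k],
            ))
    df = standardize(pd.DataFrame(rows))
    return RegressionTable(df)


@dataclass
class MLRResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    retained: list
    dropped: list
    n_obs: int

    @property
    def empty(self) -> bool:
        return self.n_obs == 0 or len(self.retained) == 0


def _check_design(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # name the offending columns via pairwise correlation / zero variance
        bad = [c for c in X.columns if c != "const" and X[c].std() == 0]
        corr = X.drop(columns=["const"], errors="ignore").corr().abs()
        np.fill_diagonal(corr.values, 0)
        for c in corr.columns:
            if (corr[c] > 1 - 1e-10).any() and c not in bad:
                bad.append(c)
        raise CollinearityError(bad or list(X.columns))


def robust_mlr(table: RegressionTable, stepwise: bool = True, alpha: float = 0.05) -> MLRResult:
    """Robust multiple linear regression of the alpha rise on the predictor
    set: iteratively reweighted least squares with Huber's T weighting
    (t = 1.345), optionally with backward stepwise elimination of the least
    significant predictor while any p exceeds ``alpha``."""
    df = table.data
    y = df["response"].to_numpy(float)
    if len(df) == 0:
        return MLRResult(pd.Series(dtype=float), pd.Series(dtype=float),
                         pd.Series(dtype=float), [], list(PREDICTORS), 0)
    if np.std(y) == 0:
        zero = pd.Series(0.0, index=PREDICTORS)
        return MLRResult(zero, zero.copy(), pd.Series(1.0, index=PREDICTORS),
                         [], list(PREDICTORS), len(df))
    if len(df) < 3 * len(PREDICTORS):
        raise ValueError("need at least 3 rows per predictor")

    cols = list(PREDICTORS)
    dropped: list = []
    while True:
        X = sm.add_constant(df[cols])
        _check_design(X)
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_T)).fit(
            maxiter=IRLS_MAXITER, tol=IRLS_TOL, conv="coefs"
        )
        pv = fit.pvalues.drop("const")
        if not stepwise or pv.max() <= alpha or len(cols) == 1:
            if stepwise and pv.max() > alpha and len(cols) == 1:
                dropped.append(cols[0])
                cols = []
            break
        worst = pv.idxmax()
        dropped.append(worst)
        cols = [c for c in cols if c != worst]
    if not cols:
        zero = pd.Series(0.0, index=PREDICTORS)
        return MLRResult(zero, zero.copy(), pd.Series(1.0, index=PREDICTORS),
                         [], dropped, len(df))
    return MLRResult(fit.params.drop("const"), fit.bse.drop("const"),
                     fit.pvalues.drop("const"), cols, dropped, len(df))


def lowered_subset_mlr(table: RegressionTable, stepwise: bool = True) -> MLRResult:
    """robust_mlr restricted to regions whose power lowered under
    stimulation (negative response rows)."""
    sub = table.data[table.data["response"] < 0].reset_index(drop=True)
    if len(sub) == 0:
        return MLRResult(pd.Series(dtype=float), pd.Series(dtype=float),
                         pd.Series(dtype=float), [], list(PREDICTORS), 0)
    resub = RegressionTable(standardize(sub))
    return robust_mlr(resub, stepwise=stepwise)


# ---------------------------------------------------------------------------
# Wilcoxon / Holm
# ---------------------------------------------------------------------------

def holm_step_down(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down Bonferroni adjustment: reject while
    p_(i) <= alpha / (m - i + 1) in ascending order, stop at first failure."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def wilcoxon_holm(per_subject_pairs: list, alpha: float = 0.05) -> pd.DataFrame:
    """One-sided (stimulated > baseline) Wilcoxon signed-rank test per
    subject with effect sizes and Holm-corrected significance.

    ``per_subject_pairs`` is a list of (baseline, stimulated) paired arrays
    (>= 5 repetitions each).  W is the rank sum of the unfavorable (negative)
    differences, so W = 0 when stimulation wins every pair.  The rank-biserial
    correlation is (favorable - unfavorable rank sum) / total rank sum; the
    common-language effect size is the fraction of all (stim, base) cross
    comparisons favoring stimulation (ties count half).
    """
    rows = []
    for base, stim in per_subject_pairs:
        base = np.asarray(base, float)
        stim = np.asarray(stim, float)
        if base.shape != stim.shape or base.size < 5:
            raise ValueError("need >= 5 paired repetitions per subject")
        diff = stim - base
        nz = diff[diff != 0]
        cles = float(np.mean(stim[:, None] > base[None, :])
                     + 0.5 * np.mean(stim[:, None] == base[None, :]))
        if nz.size == 0:
            rows.append(dict(W=np.nan, p=np.nan, rbc=np.nan, cles=cles,
                             undefined=True))
            continue
        ranks = sstats.rankdata(np.abs(nz))
        r_pos = ranks[nz > 0].sum()
        r_neg = ranks[nz < 0].sum()
        W = float(r_neg)
        rbc = float((r_pos - r_neg) / (r_pos + r_neg))
        p = float(sstats.wilcoxon(stim, base, alternative="greater",
                                  zero_method="wilcox").pvalue)
        rows.append(dict(W=W, p=p, rbc=rbc, cles=cles, undefined=False))
    df = pd.DataFrame(rows)
    defined = ~df["undefined"]
    flags = np.zeros(len(df), dtype=bool)
    if defined.any():
        flags[defined.to_numpy()] = holm_step_down(df.loc[defined, "p"].to_numpy(), alpha)
    df["significant"] = flags
    return df
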