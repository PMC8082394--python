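"""End-to-end study orchestration.

Three experiment shapes, mirroring how the hyperpolarized gluconolactone
experiments are actually run:

* ``qc`` — solution quality control: a dynamic decay series for the
  flip-angle-corrected T1 fit, optionally a hyperpolarized/thermal spectrum
  pair for the polarization back-calculation;
* ``cell`` — cell-suspension treatment comparison: replicated single-voxel
  dynamic acquisitions for a control and a treated arm (the treated arm uses a
  reduced PGLS conversion rate), AUC ratio metrics per replicate, Welch test
  between arms;
* ``invivo`` — EPSI phantom study: per-animal grid simulation with a bolus
  input, SNR and ratio maps, ROI quantification, tumor vs contralateral
  (vs healthy) comparisons, or a day-0/4/8 longitudinal arm with a per-day
  conversion-rate multiplier.

Every stage is deterministic given the explicit seed list in the config:
replicate i uses seed list[i]; no wall-clock seeding anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import kinetics, spectra, stats, synth
from .epsi import metabolite_snr_grid, ratio_map, roi_quantify
from .spectra import apodize, integrate_peak, default_windows

__all__ = ["RunConfig", "make_seed_list", "series_to_timecourse",
           "run_qc", "run_cell_study", "run_invivo_study", "run"]

_EXPERIMENTS = ("qc", "cell", "invivo")


@dataclass
class RunConfig:
    """A study configuration: experiment kind plus a parameter mapping."""

    experiment: str
    params: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(
                f"experiment must be one of {_EXPERIMENTS}, "
                f"got {self.experiment!r}"
            )

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        d = dict(d)
        return cls(experiment=d.pop("experiment"), params=d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_seed_list(base_seed: int, n: int) -> List[int]:
    """Deterministic per-replicate seeds below 2**31 derived from one base."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def series_to_timecourse(
    series: spectra.DynamicSpectrumSeries,
    windows: Optional[List[spectra.PeakWindow]] = None,
) -> kinetics.Timecourse:
    """Integrate each metabolite window at every timepoint."""
    windows = windows if windows is not None else default_windows()
    areas = {
        w.name: np.array([integrate_peak(series[i], w)
                          for i in range(len(series))])
        for w in windows
    }
    return kinetics.Timecourse(times_s=series.times_s, areas=areas)


# ---------------------------------------------------------------------------
# QC: solution T1 and polarization
# ---------------------------------------------------------------------------

def run_qc(config: RunConfig) -> Dict:
    """Solution QC: simulate, process and fit a substrate decay series;
    optionally back-calculate polarization from a thermal reference pair.

    Parameters (config.params): ``T1_s``, ``theta_deg``, ``TR_s``,
    ``n_timepoints``, ``B0_T``, ``sigma``, ``seed``, ``lb_hz`` and an
    optional ``thermal`` block with ``true_P0_percent``, ``delay_s``,
    ``NA``, ``theta_th_deg``, ``temperature_K``.
    """
    if config.experiment != "qc":
        raise ValueError("run_qc requires a 'qc' config")
    p = config.params
    T1 = float(p.get("T1_s", 15.7))
    theta = float(p.get("theta_deg", 13.0))
    TR = float(p.get("TR_s", 3.0))
    n_t = int(p.get("n_timepoints", 30))
    B0 = float(p.get("B0_T", 11.7))
    sigma = float(p.get("sigma", 0.0))
    seed = int(p.get("seed", 0))
    lb = float(p.get("lb_hz", 5.0))

    res = synth.Resonance(synth.DELTA_GL, 173.8, 4.0, T1, theta)
    scheme = synth.AcquisitionScheme(TR_s=TR, n_timepoints=n_t,
                                     spectral_points=512, B0_T=B0)
    model = synth.KineticModel(k_pgls_per_s=0.0, k_dg_per_s=0.0,
                               k_gd_per_s=0.0, delta_gamma_ratio0=1.0,
                               M0=float(p.get("M0", 1.0)))
    try:
        dyn = synth.simulate_pool_dynamics(model, scheme, [res])
        series = synth.render_spectrum_series(
            dyn.amplitudes, scheme, [res],
            noise=synth.NoiseSpec(sigma=sigma, seed=seed))
        series = apodize(series, lb)
        window = spectra.PeakWindow(synth.DELTA_GL, res.shift_ppm, 0.5)
        areas = np.array([integrate_peak(series[i], window)
                          for i in range(len(series))])
        fit = kinetics.flip_angle_corrected_t1_fit(areas, theta, TR)
    except Exception as exc:
        raise RuntimeError(f"qc T1 stage failed: {exc}") from exc

    report: Dict = {
        "t1_fit": fit,
        "settings": {"T1_s": T1, "theta_deg": theta, "TR_s": TR,
                     "B0_T": B0, "sigma": sigma, "seed": seed, "lb_hz": lb},
    }
    if "thermal" in p:
        th = p["thermal"]
        for key in ("true_P0_percent", "delay_s"):
            if key not in th:
                raise ValueError(f"thermal block missing required key {key!r}")
        try:
            report["polarization"] = _qc_polarization(th, res, scheme, theta, B0)
        except Exception as exc:
            raise RuntimeError(f"qc polarization stage failed: {exc}") from exc
    return report


def _qc_polarization(th: Dict, res: synth.Resonance,
                     scheme: synth.AcquisitionScheme, theta_hp: float,
                     B0: float) -> kinetics.PolarizationResult:
    """Construct a consistent hyperpolarized/thermal pair and back-calculate."""
    P0 = float(th["true_P0_percent"])
    delay = float(th["delay_s"])
    NA = int(th.get("NA", 16))
    theta_th = float(th.get("theta_th_deg", 90.0))
    temperature = float(th.get("temperature_K", 298.0))
    T1 = float(th.get("T1_s", res.T1_s))
    ctx = kinetics.PolarizationContext(B0_T=B0, temperature_K=temperature)
    P_th = kinetics.thermal_polarization(ctx)

    conc = float(th.get("concentration_scale", 1.0))
    window = spectra.PeakWindow(res.name, res.shift_ppm, 0.5)
    res_th = replace(res, flip_angle_deg=theta_th)
    thermal = synth.render_thermal_spectrum(conc, scheme, res_th, P_th, NA=NA)
    # hyperpolarized polarization at first acquisition, decayed over the delay
    P_hp_acq = (P0 / 100.0) * np.exp(-delay / T1)
    amp_hp = conc * P_hp_acq * np.sin(np.deg2rad(theta_hp))
    hp_first = synth.render_spectrum_series(
        np.array([[amp_hp]]), scheme, [res])[0]
    return kinetics.back_calculate_polarization(
        hp_first_area=integrate_peak(hp_first, window),
        th_area=integrate_peak(thermal, window),
        theta_hp_deg=theta_hp,
        theta_th_deg=theta_th,
        NA_th=NA,
        delay_s=delay,
        T1_s=T1,
        ctx=ctx,
    )


# ---------------------------------------------------------------------------
# Cell-suspension treatment comparison
# ---------------------------------------------------------------------------

def _simulate_cell_replicate(k: float, scheme, resonances, sigma, seed,
                             lb_hz, windows, M0=1.0) -> kinetics.RatioMetrics:
    model = synth.KineticModel(k_pgls_per_s=k, M0=M0)
    dyn = synth.simulate_pool_dynamics(model, scheme, resonances)
    series = synth.render_spectrum_series(
        dyn.amplitudes, scheme, resonances,
        noise=synth.NoiseSpec(sigma=sigma, seed=seed))
    series = apodize(series, lb_hz)
    tc = series_to_timecourse(series, windows)
    return kinetics.compute_ratio_metrics(tc)


def product_sigma_for_snr(k: float, scheme, resonances, target_snr: float,
                          M0: float = 1.0) -> float:
    """Noise sigma giving the 6PG product peak a temporal-maximum SNR of
    ``target_snr`` in the noiseless spectra.

    The product line is the weakest metabolically informative signal (the
    hyperpolarized substrate is orders of magnitude stronger), so noise
    levels are anchored on it.
    """
    model = synth.KineticModel(k_pgls_per_s=k, M0=M0)
    dyn = synth.simulate_pool_dynamics(model, scheme, resonances)
    series = synth.render_spectrum_series(dyn.amplitudes, scheme, resonances)
    w = next(x for x in default_windows() if x.name == synth.SIX_PG)
    mask = (series.axis_ppm >= w.lo_ppm) & (series.axis_ppm <= w.hi_ppm)
    height = float(series.values[:, mask].real.max())
    if height <= 0:
        raise ValueError("no product signal; cannot anchor noise on its SNR")
    return height / target_snr


def run_cell_study(config: RunConfig) -> Dict:
    """Control vs treated cell study: per-replicate AUC ratios + Welch tests.

    Parameters: ``k_control``, ``k_treated`` (1/s), ``n_replicates``,
    ``seed`` (or explicit ``seeds_control``/``seeds_treated`` lists),
    ``lb_hz``, scheme overrides (``TR_s``, ``n_timepoints``), and either an
    explicit ``sigma`` or a ``product_snr`` target (default 50) that anchors
    the noise level on the control arm's noiseless 6PG peak.
    """
    if config.experiment != "cell":
        raise ValueError("run_cell_study requires a 'cell' config")
    p = config.params
    k_control = float(p.get("k_control", 0.01))
    k_treated = float(p.get("k_treated", 0.6 * k_control))
    n_rep = int(p.get("n_replicates", 3))
    lb = float(p.get("lb_hz", 5.0))
    scheme = synth.AcquisitionScheme(
        TR_s=float(p.get("TR_s", 3.0)),
        n_timepoints=int(p.get("n_timepoints", 100)),
        spectral_points=int(p.get("spectral_points", 1024)),
        B0_T=float(p.get("B0_T", 11.7)),
    )
    resonances = synth.default_resonances("cell")
    windows = default_windows()
    if "sigma" in p:
        sigma = float(p["sigma"])
    else:
        sigma = product_sigma_for_snr(k_control, scheme, resonances,
                                      float(p.get("product_snr", 50.0)))
    base = int(p.get("seed", 0))
    seeds_c = p.get("seeds_control", make_seed_list(base, n_rep))
    seeds_t = p.get("seeds_treated", make_seed_list(base + 1, n_rep))

    rows = []
    for arm, k, seeds in (("control", k_control, seeds_c),
                          ("treated", k_treated, seeds_t)):
        for i, s in enumerate(seeds):
            m = _simulate_cell_replicate(k, scheme, resonances, sigma,
                                         int(s), lb, windows)
            rows.append({"arm": arm, "replicate": i, "k_per_s": k,
                         "ratio_dgl": m.ratio_dgl,
                         "ratio_total": m.ratio_total,
                         "auc_6pg": m.auc_6pg, "auc_dgl": m.auc_dgl,
                         "auc_ggl": m.auc_ggl})
    metrics = pd.DataFrame(rows)
    comparisons = {}
    for metric in ("ratio_dgl", "ratio_total"):
        a = metrics.loc[metrics.arm == "control", metric].to_numpy()
        b = metrics.loc[metrics.arm == "treated", metric].to_numpy()
        comparisons[metric] = stats.welch_t_test(a, b)
    return {"metrics": metrics, "comparisons": comparisons}


# ---------------------------------------------------------------------------
# In vivo EPSI studies
# ---------------------------------------------------------------------------

def _invivo_scheme(p: Dict) -> synth.AcquisitionScheme:
    return synth.AcquisitionScheme(
        TR_s=float(p.get("TR_s", 3.0)),
        n_timepoints=int(p.get("n_timepoints", 40)),
        spectral_points=int(p.get("spectral_points", 128)),
        B0_T=float(p.get("B0_T", 3.0)),
        mode="epsi_grid",
    )


def _simulate_animal(phantom, scheme, resonances, model, sigma, seed,
                     scale_cv=0.0):
    """One animal's EPSI acquisition.

    ``scale_cv`` models the injection-to-injection variability of the
    delivered polarization (the measured dissolution polarization varies by
    ~18% between preparations) as a per-animal lognormal scale on M0; it
    cancels in product/substrate ratios but spreads absolute SNR values.
    """
    if scale_cv > 0:
        rng = np.random.default_rng([int(seed), 1])
        model = replace(model,
                        M0=model.M0 * float(rng.lognormal(0.0, scale_cv)))
    return synth.simulate_epsi_dataset(
        phantom, model, scheme, resonances,
        noise=synth.NoiseSpec(sigma=sigma, seed=seed))


def _animal_region_metrics(ds, windows, noise_voxel, snr_floor) -> Dict:
    w = {x.name: x for x in windows}
    sub = metabolite_snr_grid(ds, w[synth.DELTA_GL], noise_voxel)
    gam = metabolite_snr_grid(ds, w[synth.GAMMA_GL], noise_voxel)
    prod = metabolite_snr_grid(ds, w[synth.SIX_PG], noise_voxel)
    ratio = ratio_map(prod, sub, snr_floor=snr_floor).values
    ratio_tot = ratio_map(prod, sub + gam, snr_floor=snr_floor).values
    out = {}
    for region, mask in ds.masks.items():
        if region == "outside" or not mask.any():
            continue
        vol = ds.voxel_volume_mm3
        out[region] = {
            "snr_dgl": roi_quantify(sub, mask, vol).mean,
            "snr_6pg": roi_quantify(prod, mask, vol).mean,
            "ratio_dgl": roi_quantify(ratio, mask, vol).mean,
            "ratio_total": roi_quantify(ratio_tot, mask, vol).mean,
        }
    return out


def run_invivo_study(config: RunConfig) -> Dict:
    """In vivo EPSI study: per-animal phantoms, maps, ROI table, Welch tests.

    Cross-sectional mode (default): ``n_animals`` tumor-bearing phantoms and
    ``n_healthy`` tumor-free phantoms; tumor vs contralateral (vs healthy)
    comparisons of the product/substrate ratio and substrate SNR.
    Longitudinal mode (``days`` mapping day -> k multiplier): each animal is
    re-simulated per day with the tumor conversion rate scaled by the day's
    multiplier, mimicking a treatment-response study.
    """
    if config.experiment != "invivo":
        raise ValueError("run_invivo_study requires an 'invivo' config")
    p = config.params
    n_animals = int(p.get("n_animals", 6))
    n_healthy = int(p.get("n_healthy", 0))
    sigma = float(p.get("sigma", 0.005))
    snr_floor = float(p.get("snr_floor", 5.0))
    k_tumor = float(p.get("k_tumor", 0.02))
    k_background = float(p.get("k_background", 0.005))
    scheme = _invivo_scheme(p)
    resonances = synth.default_resonances("invivo")
    windows = default_windows()
    noise_voxel = tuple(p.get("noise_voxel", (0, 0)))
    scale_cv = float(p.get("animal_scale_cv", 0.18))
    base = int(p.get("seed", 0))
    model = synth.KineticModel(
        k_pgls_per_s=k_background,
        M0=float(p.get("M0", 1.0)),
        bolus_start_s=0.0,
        bolus_duration_s=float(p.get("bolus_duration_s", 15.0)),
    )

    days = p.get("days")
    if days:  # longitudinal treatment-response mode
        seeds = p.get("seeds", make_seed_list(base, n_animals * len(days)))
        rows = []
        si = 0
        for day, mult in sorted(days.items()):
            phantom = synth.reference_phantom(
                k_tumor=k_tumor * float(mult), k_background=k_background)
            for animal in range(n_animals):
                ds = _simulate_animal(phantom, scheme, resonances, model,
                                      sigma, int(seeds[si]),
                                      scale_cv=scale_cv); si += 1
                for region, vals in _animal_region_metrics(
                        ds, windows, noise_voxel, snr_floor).items():
                    for metric, v in vals.items():
                        rows.append({"day": int(day), "animal": animal,
                                     "region": region, "metric": metric,
                                     "value": v})
        table = pd.DataFrame(rows)
        comparisons = {}
        day_list = sorted({int(d) for d in days})
        sel = table[(table.region == "tumor") & (table.metric == "ratio_dgl")]
        for d0, d1 in zip(day_list[:-1], day_list[1:]):
            a = sel.loc[sel.day == d0, "value"].to_numpy()
            b = sel.loc[sel.day == d1, "value"].to_numpy()
            comparisons[f"tumor_ratio_dgl_day{d0}_vs_day{d1}"] = \
                stats.welch_t_test(a, b)
        return {"table": table, "comparisons": comparisons}

    # cross-sectional tumor vs contralateral (vs healthy)
    seeds = p.get("seeds", make_seed_list(base, n_animals + n_healthy))
    phantom = synth.reference_phantom(k_tumor=k_tumor,
                                      k_background=k_background)
    healthy_phantom = synth.reference_phantom(k_tumor=k_background,
                                              k_background=k_background)
    rows = []
    for animal in range(n_animals):
        ds = _simulate_animal(phantom, scheme, resonances, model, sigma,
                              int(seeds[animal]), scale_cv=scale_cv)
        for region, vals in _animal_region_metrics(
                ds, windows, noise_voxel, snr_floor).items():
            for metric, v in vals.items():
                rows.append({"group": "tumor_bearing", "animal": animal,
                             "region": region, "metric": metric, "value": v})
    for animal in range(n_healthy):
        ds = _simulate_animal(healthy_phantom, scheme, resonances, model,
                              sigma, int(seeds[n_animals + animal]),
                              scale_cv=scale_cv)
        vals = _animal_region_metrics(ds, windows, noise_voxel, snr_floor)
        # in a tumor-free control any brain region is "healthy brain"
        for metric, v in vals["contralateral"].items():
            rows.append({"group": "healthy", "animal": animal,
                         "region": "healthy_brain", "metric": metric,
                         "value": v})
    table = pd.DataFrame(rows)

    def _vals(region, metric):
        sel = table[(table.region == region) & (table.metric == metric)]
        return sel["value"].to_numpy()

    comparisons = {}
    for metric in ("ratio_dgl", "ratio_total", "snr_dgl", "snr_6pg"):
        comparisons[f"{metric}_tumor_vs_contralateral"] = stats.welch_t_test(
            _vals("tumor", metric), _vals("contralateral", metric))
        if n_healthy >= 2:
            comparisons[f"{metric}_tumor_vs_healthy"] = stats.welch_t_test(
                _vals("tumor", metric), _vals("healthy_brain", metric))
    return {"table": table, "comparisons": comparisons}


def run(config: RunConfig) -> Dict:
    """Dispatch on the experiment kind."""
    return {"qc": run_qc, "cell": run_cell_study,
            "invivo": run_invivo_study}[config.experiment](config)
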