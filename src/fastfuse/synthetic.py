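"""Synthetic inputs for every analysis stage.

Generators emulate the four experimental input kinds so the whole pipeline
is testable without downloads: dominant-negative titration curves drawn
from the cluster/site fusion model with Gaussian replicate noise;
widefield-like three-channel FRET image sets with Gaussian-PSF puncta,
spectral bleed-through, background and read noise; sigmoidal liposome
lipid-mixing traces; and Poisson syncytial-nucleus field counts.  Every
generator is deterministic given its seed and emits a ground-truth record.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .assay_stats import FluorescenceTrace
from .pixel_fret import ChannelImage, FretImageSet
from .stoichiometry import (
    StoichModel,
    TitrationCurve,
    TitrationPoint,
    fit_stoichiometry,
    predict_fusion,
)

__all__ = [
    "FretSimConfig",
    "FRET_SCENARIOS",
    "simulate_titration",
    "simulate_fret_images",
    "simulate_lipid_trace",
    "simulate_field_counts",
    "default_f_grid",
    "titration_recovery_study",
]

FRET_SCENARIOS = (
    "interacting",
    "non_interacting",
    "donor_only",
    "acceptor_only",
    "diffuse_depleted",
)


def default_f_grid() -> np.ndarray:
    """11 functional fractions evenly spanning 0..1 (the titration design)."""
    return np.linspace(0.0, 1.0, 11)


def simulate_titration(
    model: StoichModel,
    f_grid: Optional[Sequence[float]] = None,
    noise_sd: float = 0.03,
    replicates: int = 1,
    experiments: int = 3,
    seed: int = 0,
) -> TitrationCurve:
    """Titration curve from the cluster/site model plus Gaussian replicate noise.

    Activities are predict_fusion(f) + N(0, noise_sd), floored at 0, with
    ``replicates`` points per f per experiment.  noise_sd = 0 reproduces the
    model exactly; the same seed reproduces the same curve bit-for-bit.
    """
    if f_grid is None:
        f_grid = default_f_grid()
    f_grid = np.asarray(f_grid, dtype=float)
    if f_grid.size == 0:
        raise ValueError("f_grid must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    points = []
    for e in range(1, experiments + 1):
        for f in f_grid:
            truth = predict_fusion(model, float(f))
            for r in range(1, replicates + 1):
                act = truth + rng.normal(0.0, noise_sd) if noise_sd > 0 else truth
                points.append(
                    TitrationPoint(
                        f=float(f),
                        activity=max(act, 0.0),
                        experiment_id=f"exp{e}",
                        field_id=f"rep{r}",
                    )
                )
    return TitrationCurve(points, normalization_reference="model-generated, f=1 mean 1")


@dataclass
class FretSimConfig:
    """Parameters of the widefield FRET image generator.

    Defaults describe a 256x256 field of view with ~260 diffraction-limited
    puncta (density 0.004 px^-2), lognormal punctum amplitudes (mean 500
    detector units, CV 0.3) over a 100 DU background with 5 DU Gaussian read
    noise, PSF sigma 1.5 px, FRET efficiency 0.3 at co-positioned puncta and
    constant bleed-through ratios bt_d = 0.15, bt_a = 0.10.
    """

    shape: tuple = (256, 256)
    puncta_density: float = 0.004  # expected puncta per pixel
    amp_mean: float = 500.0  # mean peak amplitude, detector units
    amp_cv: float = 0.3  # lognormal coefficient of variation
    psf_sigma: float = 1.5  # px
    background: float = 100.0  # DU offset per channel
    read_noise_sd: float = 5.0  # DU Gaussian read noise
    shot_noise: bool = False  # optional Poisson noise on the signal
    fret_efficiency: float = 0.3  # E: sensitized signal fraction at co-positions
    fret_model: str = "donor"  # "donor": E*donor; "geometric": E*sqrt(d*a)
    bt_donor: float = 0.15  # donor SBT ratio (constant term / prefactor)
    bt_acceptor: float = 0.10
    sbt_kind: str = "constant"  # constant | exponential
    bt_donor_b: float = 0.0  # exponential rate for donor SBT
    bt_acceptor_b: float = 0.0
    bit_depth: int = 16

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d


def _lognormal_amps(rng, n, mean, cv):
    sigma = math.sqrt(math.log(1.0 + cv**2))
    mu = math.log(mean) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, size=n)


def _render_puncta(shape, rows, cols, amps, sigma):
    """Sum of Gaussian spots with peak amplitudes ``amps`` at subpixel positions."""
    img = np.zeros(shape, dtype=float)
    half = int(math.ceil(4 * sigma))
    for r, c, a in zip(rows, cols, amps):
        r0, r1 = max(int(r) - half, 0), min(int(r) + half + 1, shape[0])
        c0, c1 = max(int(c) - half, 0), min(int(c) + half + 1, shape[1])
        if r0 >= r1 or c0 >= c1:
            continue
        yy = np.arange(r0, r1)[:, None] - r
        xx = np.arange(c0, c1)[None, :] - c
        img[r0:r1, c0:c1] += a * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    return img


def _sbt_signal(signal, ratio, rate, kind):
    if kind == "constant":
        return ratio * signal
    if kind == "exponential":
        return ratio * np.exp(rate * signal) * signal
    raise ValueError(f"unknown sbt_kind {kind!r}")


def simulate_fret_images(
    scenario: str,
    n_images: int = 10,
    config: Optional[FretSimConfig] = None,
    seed: int = 0,
    condition: str = "",
    experiment_id: str = "",
) -> tuple[list[FretImageSet], dict]:
    """Generate three-channel FRET image sets for a named scenario.

    Scenarios
    ---------
    interacting
        Donor and acceptor puncta co-positioned; the FRET channel carries a
        true sensitized signal (E * donor amplitude by default) plus SBT.
    non_interacting
        Two independent punctum sets; the FRET channel is SBT only.
    donor_only / acceptor_only
        One fluorophore plus its SBT contribution.
    diffuse_depleted
        Spatially uniform fluorophore (cholesterol-depleted phenotype),
        matched total flux, no true FRET.

    All channels receive the background offset and Gaussian read noise, are
    clipped at 0 and saturated at the bit-depth ceiling.  Returns the image
    sets and a ground-truth record of every generating parameter.
    """
    if scenario not in FRET_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {FRET_SCENARIOS}")
    cfg = config or FretSimConfig()
    rng = np.random.default_rng(seed)
    area = cfg.shape[0] * cfg.shape[1]
    ceiling = float(2**cfg.bit_depth - 1)
    sets = []
    for i in range(n_images):
        donor_sig = np.zeros(cfg.shape)
        acceptor_sig = np.zeros(cfg.shape)
        fret_true = np.zeros(cfg.shape)

        def draw_puncta():
            n = rng.poisson(cfg.puncta_density * area)
            rows = rng.uniform(0, cfg.shape[0], n)
            cols = rng.uniform(0, cfg.shape[1], n)
            amps = _lognormal_amps(rng, n, cfg.amp_mean, cfg.amp_cv)
            return rows, cols, amps

        if scenario == "interacting":
            rows, cols, d_amps = draw_puncta()
            a_amps = _lognormal_amps(rng, len(d_amps), cfg.amp_mean, cfg.amp_cv)
            donor_sig = _render_puncta(cfg.shape, rows, cols, d_amps, cfg.psf_sigma)
            acceptor_sig = _render_puncta(cfg.shape, rows, cols, a_amps, cfg.psf_sigma)
            if cfg.fret_model == "donor":
                fret_true = cfg.fret_efficiency * donor_sig
            elif cfg.fret_model == "geometric":
                fret_true = cfg.fret_efficiency * np.sqrt(donor_sig * acceptor_sig)
            else:
                raise ValueError(f"unknown fret_model {cfg.fret_model!r}")
        elif scenario == "non_interacting":
            r1, c1, a1 = draw_puncta()
            donor_sig = _render_puncta(cfg.shape, r1, c1, a1, cfg.psf_sigma)
            r2, c2, a2 = draw_puncta()
            acceptor_sig = _render_puncta(cfg.shape, r2, c2, a2, cfg.psf_sigma)
        elif scenario == "donor_only":
            r1, c1, a1 = draw_puncta()
            donor_sig = _render_puncta(cfg.shape, r1, c1, a1, cfg.psf_sigma)
        elif scenario == "acceptor_only":
            r2, c2, a2 = draw_puncta()
            acceptor_sig = _render_puncta(cfg.shape, r2, c2, a2, cfg.psf_sigma)
        elif scenario == "diffuse_depleted":
            # same expected flux as the punctate scenarios, spread uniformly
            flux = cfg.puncta_density * cfg.amp_mean * 2 * math.pi * cfg.psf_sigma**2
            donor_sig = np.full(cfg.shape, flux)
            acceptor_sig = np.full(cfg.shape, flux)

        fret_sig = (
            fret_true
            + _sbt_signal(donor_sig, cfg.bt_donor, cfg.bt_donor_b, cfg.sbt_kind)
            + _sbt_signal(acceptor_sig, cfg.bt_acceptor, cfg.bt_acceptor_b, cfg.sbt_kind)
        )

        channels = {}
        for role, sig in (("donor", donor_sig), ("acceptor", acceptor_sig), ("fret", fret_sig)):
            out = sig.copy()
            if cfg.shot_noise:
                out = rng.poisson(np.clip(out, 0, None)).astype(float)
            out = out + cfg.background + rng.normal(0.0, cfg.read_noise_sd, cfg.shape)
            channels[role] = ChannelImage(
                np.clip(out, 0.0, ceiling), role, cfg.bit_depth
            )
        sets.append(
            FretImageSet(
                donor=channels["donor"],
                acceptor=channels["acceptor"],
                fret=channels["fret"],
                cell_id=f"{scenario}_{i:03d}",
                condition=condition or scenario,
            )
        )
    ground_truth = {
        "scenario": scenario,
        "n_images": n_images,
        "seed": seed,
        "experiment_id": experiment_id,
        "config": cfg.to_dict(),
    }
    return sets, ground_truth


def simulate_lipid_trace(
    rate: float,
    extent: float,
    f0: float = 100.0,
    f_max: float = 600.0,
    noise_sd: float = 0.0,
    duration: float = 600.0,
    n_points: int = 120,
    seed: int = 0,
    label: str = "",
) -> FluorescenceTrace:
    """Exponential-approach dequenching trace.

    F(t) = f0 + extent*(f_max - f0)*(1 - exp(-rate*t)) + N(0, noise_sd); the
    percent-lipid-mixing endpoint approaches 100*extent as t -> inf and
    noise -> 0.  Durations span up to ten minutes by default.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not 0.0 <= extent <= 1.0:
        raise ValueError("extent must lie in [0, 1]")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    f = f0 + extent * (f_max - f0) * (1.0 - np.exp(-rate * t))
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, t.shape)
    return FluorescenceTrace(time=t, intensity=f, label=label)


def titration_recovery_study(
    model: StoichModel,
    n_curves: int = 100,
    noise_sd: float = 0.03,
    replicates: int = 1,
    experiments: int = 3,
    seed: int = 0,
) -> dict:
    """Simulate-and-refit study of (n, s) recovery from noisy titrations.

    Generates ``n_curves`` independent titration curves from ``model`` on the
    default 11-point f-grid (``experiments`` experiments each) and refits
    every one, returning the per-curve estimates plus their means and the
    mean reported standard errors.  Curve seeds are derived from ``seed``.
    """
    n_hat, s_hat, se_n, se_s = [], [], [], []
    for i in range(n_curves):
        curve_seed = (seed * 100_003 + i) % 2**31
        curve = simulate_titration(
            model,
            noise_sd=noise_sd,
            replicates=replicates,
            experiments=experiments,
            seed=curve_seed,
        )
        fit = fit_stoichiometry(curve)
        n_hat.append(fit.model.n)
        s_hat.append(fit.model.s)
        se_n.append(fit.se_n)
        se_s.append(fit.se_s)
    return {
        "n_hat": n_hat,
        "s_hat": s_hat,
        "mean_n": float(np.mean(n_hat)),
        "mean_s": float(np.mean(s_hat)),
        "mean_se_n": float(np.mean(se_n)),
        "mean_se_s": float(np.mean(se_s)),
        "n_curves": n_curves,
        "noise_sd": noise_sd,
    }


def simulate_field_counts(
    mean_count: float,
    n_fields: int = 5,
    n_experiments: int = 3,
    seed: int = 0,
) -> dict:
    """Poisson syncytial-nucleus counts: 5 fields per well, 3 experiments."""
    if mean_count < 0:
        raise ValueError("mean_count must be >= 0")
    rng = np.random.default_rng(seed)
    return {
        f"exp{e}": rng.poisson(mean_count, n_fields).tolist()
        for e in range(1, n_experiments + 1)
    }
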