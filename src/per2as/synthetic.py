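"""Synthetic antiphasic circadian time courses (mouse-liver-style stand-ins).

Mouse-liver measurements of *Per2* and *Per2AS* show ~24 h rhythms, an
antisense peak at roughly 5% of the sense peak, and a ~12 h offset between
the two peaks.  Those points exist only as plotted symbols, so this module
generates equivalent datasets: either idealized raised-cosine waveforms or
samples of the model's own attractor, with multiplicative log-normal noise
(expression data are positive and heteroscedastic) or optional additive
Gaussian noise.  Every dataset carries metadata sufficient to regenerate it
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import MutantSpec, WILD_TYPE
from .parameters import ParameterSet
from .rhythms import Trajectory, simulate, summarize_limit_cycle

__all__ = [
    "TimecourseDataset",
    "generate_waveform_dataset",
    "generate_model_dataset",
    "regenerate_dataset",
]

DEFAULT_SAMPLING_H = 2.0
DEFAULT_N_DAYS = 2.0


@dataclass(frozen=True)
class TimecourseDataset:
    """Sampled rhythmic data: times (h) x species, in relative units."""

    times: np.ndarray
    values: Mapping[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        for sp, v in self.values.items():
            if len(v) != len(self.times):
                raise ValueError(f"species {sp!r} length mismatch")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"species {sp!r} has non-finite values")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.values.keys())

    def peak_time(self, species: str) -> float:
        """Peak time by quadratic interpolation around the sample maximum."""
        v = np.asarray(self.values[species])
        i = int(np.argmax(v))
        if i == 0 or i == len(v) - 1:
            return float(self.times[i])
        a, b, c = v[i - 1], v[i], v[i + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        return float(self.times[i] + delta * (self.times[i] - self.times[i - 1]))

    def estimate_period(self, species: str = "Per2") -> Optional[float]:
        """Autocorrelation period estimate; ``None`` when sampling is too
        coarse to resolve a cycle (aliasing guard: needs > 4 samples/cycle)."""
        v = np.asarray(self.values[species], dtype=float)
        v = v - v.mean()
        if np.allclose(v, 0):
            return None
        dt = float(np.median(np.diff(self.times)))
        n = len(v)
        ac = np.correlate(v, v, mode="full")[n - 1:]
        ac = ac / (n - np.arange(n))        # unbiased: divide by overlap
        from scipy.signal import find_peaks

        idx, _ = find_peaks(ac)
        if len(idx) == 0:
            return None
        i = int(idx[0])
        if i <= 4:                      # fewer than ~4 samples per cycle
            return None
        # refine the coarse autocorrelation lag with a least-squares
        # harmonic fit over frequency (the short window biases both the
        # raw autocorrelation peak and a plain periodogram)
        t = np.asarray(self.times, dtype=float)
        w0 = 2.0 * np.pi / (i * dt)
        omegas = np.linspace(0.8 * w0, 1.2 * w0, 241)

        def explained(w: float) -> float:
            X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
            coef, *_ = np.linalg.lstsq(X, v, rcond=None)
            fit = X @ coef
            return float(fit @ fit)

        power = np.array([explained(w) for w in omegas])
        k = int(np.argmax(power))
        if 0 < k < len(omegas) - 1:
            a, b, c = power[k - 1], power[k], power[k + 1]
            denom = a - 2 * b + c
            delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
            dw = omegas[1] - omegas[0]
            return float(2.0 * np.pi / (omegas[k] + delta * dw))
        return float(2.0 * np.pi / omegas[k])

    def phase_offset(self, s1: str = "Per2", s2: str = "Per2AS") -> Optional[float]:
        """Circular distance between the two species' peak times (h)."""
        T = self.estimate_period(s1)
        if T is None:
            return None
        d = abs(self.peak_time(s1) - self.peak_time(s2)) % T
        return min(d, T - d)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp, v in self.values.items():
            for t, x in zip(self.times, v):
                rows.append(dict(time_h=float(t), species=sp, value=float(x)))
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        """Write long-format CSV plus a JSON metadata sidecar."""
        self.to_frame().to_csv(path, index=False)
        with open(str(path) + ".json", "w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=2)

    @classmethod
    def from_csv(cls, path) -> "TimecourseDataset":
        df = pd.read_csv(path)
        times = np.array(sorted(df["time_h"].unique()), dtype=float)
        values = {}
        for sp, grp in df.groupby("species"):
            grp = grp.sort_values("time_h")
            values[str(sp)] = grp["value"].to_numpy(dtype=float)
        try:
            with open(str(path) + ".json", encoding="utf-8") as fh:
                metadata = json.load(fh)
        except FileNotFoundError:
            metadata = {}
        return cls(times, values, metadata)


def _apply_noise(clean: np.ndarray, noise_sd: float, rng: np.random.Generator,
                 model: str) -> np.ndarray:
    if noise_sd == 0:
        return clean.copy()
    if model == "lognormal":
        return clean * np.exp(rng.normal(0.0, noise_sd, size=clean.shape))
    if model == "gaussian":
        return clean + rng.normal(0.0, noise_sd, size=clean.shape)
    raise ValueError(f"unknown noise model: {model!r}")


def generate_waveform_dataset(
    period: float = 24.0,
    phase_offset: float = 12.0,
    amp_ratio: float = 0.05,
    n_days: float = DEFAULT_N_DAYS,
    sampling_interval: float = DEFAULT_SAMPLING_H,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_model: str = "lognormal",
) -> TimecourseDataset:
    """Idealized antiphasic raised-cosine dataset.

    *Per2* is a raised cosine with unit peak (peak at ``t = period/2``);
    *Per2AS* has peak ``amp_ratio`` and its peak shifted by ``phase_offset``.
    Multiplicative log-normal noise of scale ``noise_sd`` by default.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    if not 0 < amp_ratio <= 1:
        raise ValueError("amp_ratio must be in (0, 1]")
    times = np.arange(0.0, n_days * 24.0 + 1e-9, sampling_interval)
    t_peak = period / 2.0
    per2 = 0.5 * (1.0 + np.cos(2 * np.pi * (times - t_peak) / period))
    per2as = amp_ratio * 0.5 * (
        1.0 + np.cos(2 * np.pi * (times - t_peak - phase_offset) / period)
    )
    rng = np.random.default_rng(seed)
    values = {
        "Per2": _apply_noise(per2, noise_sd, rng, noise_model),
        "Per2AS": _apply_noise(per2as, noise_sd, rng, noise_model),
    }
    meta = dict(source="waveform", period=period, phase_offset=phase_offset,
                amp_ratio=amp_ratio, n_days=n_days,
                sampling_interval=sampling_interval, noise_sd=noise_sd,
                seed=seed, noise_model=noise_model)
    return TimecourseDataset(times, values, meta)


def generate_model_dataset(
    variant,
    params: ParameterSet,
    mutant: MutantSpec = WILD_TYPE,
    sampling_interval: float = DEFAULT_SAMPLING_H,
    n_days: float = DEFAULT_N_DAYS,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_model: str = "lognormal",
    species: tuple[str, ...] = ("Per2", "Per2AS"),
    transient: float = 700.0,
) -> TimecourseDataset:
    """Peak-normalized samples of the model attractor, with noise.

    Raises ``ValueError`` if the model is non-oscillatory at ``params``.
    """
    window = n_days * 24.0
    traj = simulate(variant, params, mutant,
                    t_end=transient + max(window, 250.0), transient=transient)
    summary = summarize_limit_cycle(traj)
    if not summary.oscillatory:
        raise ValueError(
            f"model is non-oscillatory at params {params.fingerprint()}; "
            "cannot generate a rhythmic dataset"
        )
    times = np.arange(0.0, window + 1e-9, sampling_interval)
    rng = np.random.default_rng(seed)
    values = {}
    for sp in species:
        x = traj.column(sp)
        clean = np.interp(times, traj.times - traj.times[0], x) / np.max(x)
        values[sp] = _apply_noise(clean, noise_sd, rng, noise_model)
    meta = dict(source="model", variant=str(traj.variant.value),
                fingerprint=params.fingerprint(),
                params=params.as_dict(), mutant=dict(
                    y4_0=mutant.y4_0, x5_0=mutant.x5_0,
                    dosage=dict(mutant.dosage)),
                sampling_interval=sampling_interval, n_days=n_days,
                noise_sd=noise_sd, seed=seed, noise_model=noise_model,
                species=list(species), transient=transient)
    return TimecourseDataset(times, values, meta)


def regenerate_dataset(metadata: Mapping) -> TimecourseDataset:
    """Rebuild a dataset exactly from its metadata."""
    meta = dict(metadata)
    source = meta.pop("source")
    if source == "waveform":
        return generate_waveform_dataset(**meta)
    if source == "model":
        params = ParameterSet(meta.pop("params"), name="regenerated")
        m = meta.pop("mutant")
        mutant = MutantSpec(y4_0=m["y4_0"], x5_0=m["x5_0"], dosage=m["dosage"])
        variant = meta.pop("variant")
        meta.pop("fingerprint", None)
        meta["species"] = tuple(meta.pop("species"))
        return generate_model_dataset(variant, params, mutant, **meta)
    raise ValueError(f"unknown dataset source: {source!r}")
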