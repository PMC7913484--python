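"""Seeded synthetic honey datasets: NIR spectra, physicochemical reference
values, pollen profiles and botanical labels.

Spectra are noisy, scatter-distorted linear mixtures of per-constituent
Gaussian absorption bands:

    spectrum_i(lam) = (sum_j c_ij * K_j(lam) + baseline_i(lam)) * (1 + m_i) + eps

with c_ij the constituent value, K_j the band profile, a random quadratic
baseline, a multiplicative scatter factor m_i, and white noise eps; each
stored spectrum is the mean of ``replicate_scans`` such realizations.
Constituent values are truncated-normal draws (clip-and-resample) with
per-honey-type mean offsets; pollen rows are Dirichlet draws per type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import ABSORBANCE, SpectraSet


class ConfigError(ValueError):
    """Invalid synthetic-generation configuration."""


PARAMETERS = ("moisture", "ec", "ph", "hmf", "diastase", "pfund",
              "L", "a", "b", "phenols", "flavonoids")

#: display names used in report tables
PARAMETER_LABELS = {
    "moisture": "Moisture (%)", "ec": "EC (µs/cm)", "ph": "pH",
    "hmf": "HMF (mg/100 g)", "diastase": "Diastase index",
    "pfund": "Pfund (mm)", "L": "L", "a": "a*", "b": "b*",
    "phenols": "Phenols (mg/100 g)", "flavonoids": "Flavonoids (mg/100 g)",
}

#: parameters that cannot be negative (a* genuinely ranges below zero)
NONNEGATIVE_PARAMETERS = frozenset(PARAMETERS) - {"a"}

HONEY_TYPES = ("heather", "chestnut", "eucalyptus", "blackberry",
               "honeydew", "multifloral")

POLLEN_TAXA = ("Castanea", "Eucalyptus", "Erica", "Rubus", "Cytisus",
               "Echium", "Trifolium", "Salix", "Other")

# pooled (mean, sd, min, max) per parameter
DEFAULT_CONSTITUENT_SPECS: dict[str, tuple[float, float, float, float]] = {
    "moisture": (17.9, 1.1, 15.5, 20.6),
    "ec": (869.2, 307.6, 302.5, 1649.5),
    "ph": (4.2, 0.3, 3.7, 4.8),
    "hmf": (0.1, 0.2, 0.0, 1.7),
    "diastase": (29.0, 9.3, 10.1, 44.0),
    "pfund": (98.2, 31.2, 41.0, 150.0),
    "L": (69.5, 10.4, 51.9, 84.5),
    "a": (7.4, 5.2, -3.1, 14.6),
    "b": (23.1, 9.2, 2.8, 36.2),
    "phenols": (126.3, 51.9, 36.3, 254.5),
    "flavonoids": (6.7, 3.2, 3.0, 16.7),
}

# per-type mean shifts: dark honeys (heather/chestnut/honeydew) run higher
# in conductivity, colour and phenolics; weights chosen so the count-weighted
# pooled mean stays close to the global target
DEFAULT_TYPE_OFFSETS: dict[str, dict[str, float]] = {
    "heather": {"ec": 250, "pfund": 30, "phenols": 45, "flavonoids": 2.5,
                "ph": 0.1, "L": -8, "a": 3.0, "b": -3},
    "chestnut": {"ec": 280, "pfund": 25, "phenols": 40, "flavonoids": 1.5,
                 "ph": 0.25, "L": -7, "a": 3.0, "b": -2},
    "eucalyptus": {"ec": -450, "pfund": -35, "phenols": -55, "flavonoids": -2.0,
                   "ph": -0.25, "L": 10, "a": -4.0, "b": 5},
    "blackberry": {"ec": -350, "pfund": -25, "phenols": -45, "flavonoids": -1.8,
                   "ph": -0.3, "L": 8, "a": -3.0, "b": 4},
    "honeydew": {"ec": 350, "pfund": 28, "phenols": 35, "flavonoids": 1.2,
                 "ph": 0.3, "L": -8, "a": 3.5, "b": -4},
    "multifloral": {"ec": -150, "pfund": -15, "phenols": -18, "flavonoids": -0.6,
                    "ph": -0.2, "L": 3.9, "a": -1.5, "b": 1},
}

# (center nm, width nm, amplitude in absorbance per concentration unit)
DEFAULT_BAND_LIBRARY: dict[str, list[tuple[float, float, float]]] = {
    "moisture": [(1450.0, 40.0, 0.02), (970.0, 30.0, 0.008)],
    "ec": [(1200.0, 60.0, 3e-4)],
    "ph": [(1100.0, 50.0, 0.05)],
    "hmf": [(1640.0, 30.0, 0.5)],
    "diastase": [(1000.0, 45.0, 0.008)],
    "pfund": [(960.0, 50.0, 0.002), (1300.0, 60.0, 0.0015)],
    "L": [(1350.0, 50.0, 0.003)],
    "a": [(1500.0, 45.0, 0.01)],
    "b": [(1560.0, 50.0, 0.008)],
    "phenols": [(1620.0, 40.0, 0.0015)],
    "flavonoids": [(1050.0, 35.0, 0.03)],
}

# shared honey-matrix absorption (water/sugar continuum): large common
# background so per-spectrum scaling corrections behave as on real spectra
DEFAULT_BACKGROUND_BANDS: list[tuple[float, float, float]] = [
    (1450.0, 120.0, 1.5),
    (1200.0, 150.0, 0.8),
    (1000.0, 400.0, 0.5),
]

# target pollen mean percentages per honey type (rows sum to 100)
DEFAULT_POLLEN_MEANS: dict[str, dict[str, float]] = {
    "blackberry": {"Rubus": 58.5, "Castanea": 26.4, "Erica": 3.0,
                   "Cytisus": 4.0, "Eucalyptus": 2.5, "Echium": 2.3,
                   "Trifolium": 2.3, "Salix": 0.5, "Other": 0.5},
    "chestnut": {"Castanea": 76.1, "Rubus": 14.2, "Cytisus": 3.0,
                 "Erica": 2.5, "Trifolium": 2.0, "Echium": 1.2,
                 "Salix": 0.5, "Eucalyptus": 0.3, "Other": 0.2},
    "eucalyptus": {"Eucalyptus": 72.8, "Cytisus": 7.0, "Castanea": 6.0,
                   "Erica": 4.0, "Rubus": 4.0, "Salix": 2.5,
                   "Echium": 0.6, "Trifolium": 0.6, "Other": 2.5},
    "heather": {"Castanea": 37.9, "Erica": 35.5, "Cytisus": 8.0,
                "Eucalyptus": 6.0, "Rubus": 6.0, "Echium": 3.0,
                "Trifolium": 1.0, "Salix": 0.6, "Other": 2.0},
    "honeydew": {"Castanea": 52.3, "Rubus": 18.6, "Cytisus": 9.0,
                 "Erica": 6.0, "Salix": 5.0, "Trifolium": 2.0,
                 "Echium": 2.0, "Eucalyptus": 1.1, "Other": 4.0},
    "multifloral": {"Castanea": 41.3, "Eucalyptus": 21.0, "Rubus": 10.0,
                    "Cytisus": 8.0, "Erica": 7.0, "Trifolium": 4.0,
                    "Salix": 3.0, "Echium": 3.0, "Other": 2.7},
}


def default_wavelengths() -> np.ndarray:
    """125 evenly spaced channels over 908-1676 nm."""
    return np.linspace(908.0, 1676.0, 125)


def _dirichlet_concentrations(precision: float) -> dict[str, np.ndarray]:
    return {
        t: np.array([DEFAULT_POLLEN_MEANS[t].get(tx, 0.0) for tx in POLLEN_TAXA])
        / 100.0 * precision
        for t in HONEY_TYPES
    }


@dataclass
class SyntheticConfig:
    n_samples: int = 100
    calibration_fraction: float = 0.84
    honey_type_counts: dict[str, int] = field(default_factory=lambda: {
        "heather": 5, "chestnut": 22, "eucalyptus": 9,
        "blackberry": 10, "honeydew": 18, "multifloral": 36})
    constituent_specs: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONSTITUENT_SPECS))
    type_offsets: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(o) for t, o in DEFAULT_TYPE_OFFSETS.items()})
    band_library: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_BAND_LIBRARY.items()})
    background_bands: list[tuple[float, float, float]] = field(
        default_factory=lambda: list(DEFAULT_BACKGROUND_BANDS))
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    scatter_model: tuple[float, float, float] = (0.05, 0.02, 0.01)
    noise_sd: float = 0.002
    replicate_scans: int = 3
    pollen_dirichlet: dict[str, np.ndarray] | None = None
    pollen_precision: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, float)
        if self.pollen_dirichlet is None:
            self.pollen_dirichlet = _dirichlet_concentrations(self.pollen_precision)
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if not 0 < self.calibration_fraction < 1:
            raise ConfigError("calibration_fraction must lie in (0, 1)")
        if sum(self.honey_type_counts.values()) != self.n_samples:
            raise ConfigError(
                f"honey_type_counts sums to {sum(self.honey_type_counts.values())}"
                f", expected n_samples={self.n_samples}")
        for t in self.honey_type_counts:
            if t not in HONEY_TYPES:
                raise ConfigError(f"honey_type_counts: unknown honey type {t!r}")
        for name, (mean, sd, lo, hi) in self.constituent_specs.items():
            if sd < 0:
                raise ConfigError(f"constituent_specs[{name!r}]: sd must be >= 0")
            if lo > hi:
                raise ConfigError(f"constituent_specs[{name!r}]: min > max")
        wl_lo, wl_hi = self.wavelengths.min(), self.wavelengths.max()
        for name, bands in self.band_library.items():
            for center, width, _amp in bands:
                if not wl_lo <= center <= wl_hi:
                    raise ConfigError(
                        f"band_library[{name!r}]: center {center} nm outside "
                        f"axis [{wl_lo}, {wl_hi}]")
                if width <= 0:
                    raise ConfigError(f"band_library[{name!r}]: width must be > 0")
        if any(s < 0 for s in self.scatter_model):
            raise ConfigError("scatter_model sds must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.replicate_scans < 1:
            raise ConfigError("replicate_scans must be >= 1")

    @property
    def parameters(self) -> list[str]:
        return list(self.constituent_specs)


@dataclass
class SyntheticDataset:
    spectra: SpectraSet
    reference: pd.DataFrame     # index sample_id, columns parameters
    pollen: pd.DataFrame        # index sample_id, columns taxa (percent)
    labels: pd.Series           # sample_id -> honey type
    split: pd.Series            # sample_id -> {"calibration", "validation"}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.spectra.sample_ids)

    def ids_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.split.loc[s] == group]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.spectra.to_csv(out / "spectra.csv")
        self.reference.to_csv(out / "reference.csv")
        self.pollen.to_csv(out / "pollen.csv")
        meta = pd.DataFrame({"honey_type": self.labels, "split": self.split})
        meta.index.name = "sample_id"
        meta.to_csv(out / "labels.csv")

    @classmethod
    def read(cls, in_dir) -> "SyntheticDataset":
        p = Path(in_dir)
        spectra = SpectraSet.read_csv(p / "spectra.csv", ABSORBANCE)
        reference = pd.read_csv(p / "reference.csv", index_col="sample_id")
        pollen = pd.read_csv(p / "pollen.csv", index_col="sample_id")
        meta = pd.read_csv(p / "labels.csv", index_col="sample_id")
        return cls(spectra, reference, pollen,
                   meta["honey_type"], meta["split"])


def _truncated_normal(rng, mean, sd, lo, hi, size, max_tries=200):
    """Clip-and-resample truncated normal draws within [lo, hi]."""
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    out = rng.normal(mean, sd, size)
    for _ in range(max_tries):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, lo, hi)


def band_profile(wavelengths: np.ndarray,
                 bands: list[tuple[float, float, float]]) -> np.ndarray:
    """Sum of Gaussian absorption bands evaluated on the axis."""
    wl = np.asarray(wavelengths, float)
    k = np.zeros_like(wl)
    for center, width, amp in bands:
        k += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return k


def _labels_for(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    ids, labels = [], []
    i = 1
    for t in HONEY_TYPES:
        for _ in range(config.honey_type_counts.get(t, 0)):
            ids.append(f"S{i:03d}")
            labels.append(t)
            i += 1
    return ids, labels


def generate_reference(config: SyntheticConfig, labels: list[str],
                       rng: np.random.Generator) -> pd.DataFrame:
    labels_arr = np.asarray(labels)
    n = labels_arr.size
    data = {}
    for name, (mean, sd, lo, hi) in config.constituent_specs.items():
        col = np.empty(n)
        for t in HONEY_TYPES:
            mask = labels_arr == t
            if not mask.any():
                continue
            offset = config.type_offsets.get(t, {}).get(name, 0.0)
            col[mask] = _truncated_normal(rng, mean + offset, sd, lo, hi,
                                          int(mask.sum()))
        data[name] = col
    return pd.DataFrame(data)


def generate_pollen_profiles(config: SyntheticConfig, labels,
                             rng: np.random.Generator | None = None,
                             seed=None) -> pd.DataFrame:
    """Per-type Dirichlet pollen percentages; every row sums to 100."""
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = list(labels)
    unknown = set(labels) - set(HONEY_TYPES)
    if unknown:
        raise ConfigError(f"unknown honey types in labels: {sorted(unknown)}")
    rows = np.empty((len(labels), len(POLLEN_TAXA)))
    for i, t in enumerate(labels):
        alpha = np.maximum(config.pollen_dirichlet[t], 1e-3)
        rows[i] = rng.dirichlet(alpha) * 100.0
    return pd.DataFrame(rows, columns=list(POLLEN_TAXA))


def generate_spectra(config: SyntheticConfig, reference: pd.DataFrame,
                     rng: np.random.Generator) -> np.ndarray:
    wl = config.wavelengths
    u = ((wl - wl.mean()) / (np.ptp(wl) / 2)) if wl.size > 1 else np.zeros_like(wl)
    profiles = {name: band_profile(wl, bands)
                for name, bands in config.band_library.items()}
    mult_sd, add_sd, quad_sd = config.scatter_model
    background = band_profile(wl, config.background_bands)
    n = len(reference)
    out = np.zeros((n, wl.size))
    for i in range(n):
        signal = background.copy()
        for name, profile in profiles.items():
            if name in reference.columns:
                signal += float(reference.iloc[i][name]) * profile
        if not (mult_sd or add_sd or quad_sd or config.noise_sd):
            out[i] = signal  # replicates are identical; keep the exact mixture
            continue
        acc = np.zeros_like(wl)
        for _ in range(config.replicate_scans):
            b0 = rng.normal(0.0, add_sd) if add_sd else 0.0
            b1 = rng.normal(0.0, quad_sd) if quad_sd else 0.0
            b2 = rng.normal(0.0, quad_sd) if quad_sd else 0.0
            m = rng.normal(0.0, mult_sd) if mult_sd else 0.0
            baseline = b0 + b1 * u + b2 * u ** 2
            eps = (rng.normal(0.0, config.noise_sd, wl.size)
                   if config.noise_sd else 0.0)
            acc += (signal + baseline) * (1.0 + m) + eps
        out[i] = acc / config.replicate_scans
    return out


def _stratified_split(labels: list[str], fraction: float,
                      rng: np.random.Generator) -> list[str]:
    """Per-type largest-remainder allocation of calibration counts."""
    labels_arr = np.asarray(labels)
    n = labels_arr.size
    n_cal = int(round(fraction * n))
    n_cal = min(max(n_cal, 1), n - 1)
    types = [t for t in HONEY_TYPES if (labels_arr == t).any()]
    counts = {t: int(np.sum(labels_arr == t)) for t in types}
    exact = {t: fraction * counts[t] for t in types}
    base = {t: int(np.floor(exact[t])) for t in types}
    short = n_cal - sum(base.values())
    order = sorted(types, key=lambda t: exact[t] - base[t], reverse=True)
    for t in order[:max(short, 0)]:
        base[t] += 1
    assign = np.array(["validation"] * n, dtype=object)
    for t in types:
        idx = np.flatnonzero(labels_arr == t)
        chosen = rng.choice(idx, size=min(base[t], idx.size), replace=False)
        assign[chosen] = "calibration"
    # largest-remainder may over/undershoot by rounding; rebalance randomly
    while int(np.sum(assign == "calibration")) > n_cal:
        cal_idx = np.flatnonzero(assign == "calibration")
        assign[rng.choice(cal_idx)] = "validation"
    while int(np.sum(assign == "calibration")) < n_cal:
        val_idx = np.flatnonzero(assign == "validation")
        assign[rng.choice(val_idx)] = "calibration"
    return assign.tolist()


def split_calibration_validation(dataset: SyntheticDataset, fraction: float,
                                 seed=0) -> SyntheticDataset:
    """Reassign the calibration/validation split, stratified by honey type."""
    if not 0 < fraction < 1:
        raise ConfigError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    assign = _stratified_split(list(dataset.labels), fraction, rng)
    split = pd.Series(assign, index=dataset.labels.index, name="split")
    return SyntheticDataset(dataset.spectra, dataset.reference,
                            dataset.pollen, dataset.labels, split)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Deterministic synthetic dataset for a given config and seed."""
    config.validate()
    seq = np.random.SeedSequence(config.seed)
    rng_ref, rng_spec, rng_pollen, rng_split = (
        np.random.default_rng(s) for s in seq.spawn(4))
    ids, labels = _labels_for(config)
    reference = generate_reference(config, labels, rng_ref)
    reference.index = pd.Index(ids, name="sample_id")
    values = generate_spectra(config, reference, rng_spec)
    spectra = SpectraSet(ids, config.wavelengths, values, ABSORBANCE)
    pollen = generate_pollen_profiles(config, labels, rng=rng_pollen)
    pollen.index = pd.Index(ids, name="sample_id")
    label_s = pd.Series(labels, index=pollen.index, name="honey_type")
    assign = _stratified_split(labels, config.calibration_fraction, rng_split)
    split = pd.Series(assign, index=pollen.index, name="split")
    return SyntheticDataset(spectra, reference, pollen, label_s, split)
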