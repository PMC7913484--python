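"""Spectral data container and CSV round-tripping.

A :class:`SpectraSet` holds one spectrum per sample on a shared, strictly
increasing wavelength axis. Values are either raw diffuse reflectance
(``representation="reflectance"``) or absorbance-like log10(1/R)
(``representation="absorbance"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

REFLECTANCE = "reflectance"
ABSORBANCE = "absorbance"


class SpectraError(ValueError):
    """Invalid spectra container or out-of-domain values."""


@dataclass
class SpectraSet:
    sample_ids: list[str]
    wavelengths: np.ndarray  # (n_channels,), nm, strictly increasing
    values: np.ndarray       # (n_samples, n_channels)
    representation: str = ABSORBANCE

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.sample_ids), self.wavelengths.size):
            raise SpectraError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavelengths.size} channels"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise SpectraError("values contain NaN or infinite entries")
        if self.representation not in (REFLECTANCE, ABSORBANCE):
            raise SpectraError(f"unknown representation {self.representation!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_channels(self) -> int:
        return self.wavelengths.size

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            list(self.sample_ids),
            self.wavelengths.copy(),
            self.values.copy(),
            self.representation,
        )

    def with_values(self, values: np.ndarray,
                    wavelengths: np.ndarray | None = None,
                    representation: str | None = None) -> "SpectraSet":
        """New set sharing ids, with replaced values (and optionally axis)."""
        return SpectraSet(
            list(self.sample_ids),
            self.wavelengths.copy() if wavelengths is None else np.asarray(wavelengths, float),
            np.asarray(values, float),
            self.representation if representation is None else representation,
        )

    def subset(self, ids: Sequence[str]) -> "SpectraSet":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise SpectraError(f"unknown sample ids: {missing}")
        rows = [index[s] for s in ids]
        return SpectraSet(list(ids), self.wavelengths.copy(),
                          self.values[rows], self.representation)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{w:g}" for w in self.wavelengths])
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, representation: str = ABSORBANCE) -> "SpectraSet":
        if "sample_id" not in df.columns:
            raise SpectraError("spectra table must have a 'sample_id' column")
        wl_cols = [c for c in df.columns if c != "sample_id"]
        wavelengths = np.array([float(c) for c in wl_cols])
        order = np.argsort(wavelengths)
        return cls(
            df["sample_id"].astype(str).tolist(),
            wavelengths[order],
            df[wl_cols].to_numpy(dtype=float)[:, order],
            representation,
        )

    @classmethod
    def read_csv(cls, path, representation: str = ABSORBANCE) -> "SpectraSet":
        return cls.from_frame(pd.read_csv(path), representation)
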