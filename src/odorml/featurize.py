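"""Turn peak-list spectra and SMILES strings into fixed-length features.

Three modalities, mirroring what an electronic-nose / QSAR practitioner can
obtain for an odorant molecule:

* **Vibrational spectra (VS)** — a peak list of (wavenumber, intensity)
  pairs is projected onto a bounded frequency scale (BFS, 1-4000 cm^-1 by
  default), broadened with a unit-area Gaussian kernel of width sigma
  (default 10 cm^-1), sampled every L cm^-1 (default 5, giving 800 bins) and
  max-normalised to [0, 1].  The broadening lets molecules with slightly
  shifted normal modes be compared bin-by-bin.
* **Mass spectra (MS)** — intensities at integer m/z are windowed to
  50-262 m/z inclusive (213 bins; below 50 sits odorless small-molecule
  background, above 262 low-volatility compounds) and divided by the
  maximum intensity inside the window.
* **Fingerprints (FP)** — 1024-bit path-based (Daylight-style) binary
  fingerprints computed from SMILES with RDKit.

Modalities are fused by plain column-wise concatenation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PeakList",
    "SmoothingConfig",
    "SpectrumVector",
    "smooth_vibrational",
    "window_mass_spectrum",
    "smiles_to_fingerprint",
    "fuse_features",
]

SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass
class PeakList:
    """Raw (position, intensity) pairs for one molecule's VS or MS.

    Positions are wavenumbers in cm^-1 for vibrational spectra or m/z values
    for mass spectra; intensities are arbitrary non-negative units.
    """

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).ravel()
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have equal length")
        if (self.intensities < 0).any():
            raise ValueError("intensities must be non-negative")
        if (self.positions <= 0).any():
            raise ValueError("positions must be strictly positive")

    def __len__(self) -> int:
        return self.positions.size


@dataclass
class SmoothingConfig:
    """Gaussian smoothing / sampling parameters for vibrational spectra.

    sigma : kernel width in cm^-1 (default 10)
    L : sampling increment in cm^-1 (default 5)
    bfs_lo, bfs_hi : endpoints of the bounded frequency scale in cm^-1
        (defaults 1 and 4000).  The grid holds floor(bfs_hi / L) points at
        L, 2L, ..., so the defaults give exactly 800 descriptors.
    """

    sigma: float = 10.0
    L: float = 5.0
    bfs_lo: float = 1.0
    bfs_hi: float = 4000.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.bfs_lo >= self.bfs_hi:
            raise ValueError("bfs_lo must be below bfs_hi")

    @property
    def grid(self) -> np.ndarray:
        """Bin centers k*L for k = 1..floor(bfs_hi / L)."""
        n = int(np.floor(self.bfs_hi / self.L))
        return self.L * np.arange(1, n + 1, dtype=float)


@dataclass
class SpectrumVector:
    """A fixed-length featurized spectrum with its sampling grid."""

    values: np.ndarray
    kind: str  # "VS" or "MS"
    grid: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return self.values.size


def smooth_vibrational(
    peaks: PeakList,
    cfg: SmoothingConfig | None = None,
    normalize: bool = True,
) -> SpectrumVector:
    """Project a vibrational peak list onto the BFS grid via Gaussian smoothing.

    The continuous signal is ``s(x) = sum_k I_k * K(x; pos_k, sigma)`` with
    the unit-area Gaussian kernel ``K(x; m, s) = exp(-(x-m)^2 / (2 s^2)) /
    (s sqrt(2 pi))``, evaluated at every grid point and, when ``normalize``
    is set, divided by its maximum so values lie in [0, 1].  An empty peak
    list yields an all-zero vector.  Peaks outside the BFS contribute through
    the kernel tail; the kernel is evaluated exactly (no truncation).
    """
    cfg = cfg or SmoothingConfig()
    grid = cfg.grid
    if len(peaks) == 0:
        return SpectrumVector(np.zeros(grid.size), "VS", grid)
    # (n_grid, n_peaks) kernel matrix; exact evaluation is cheap at this scale
    d = grid[:, None] - peaks.positions[None, :]
    kern = np.exp(-(d * d) / (2.0 * cfg.sigma**2)) / (cfg.sigma * SQRT_2PI)
    values = kern @ peaks.intensities
    if normalize:
        m = values.max()
        if m > 0:
            values = values / m
    return SpectrumVector(values, "VS", grid)


def window_mass_spectrum(
    peaks: PeakList,
    lo: int = 50,
    hi: int = 262,
    round_mz: bool = True,
) -> SpectrumVector:
    """Bin a mass spectrum to the inclusive [lo, hi] m/z window and normalise.

    Returns a vector of ``hi - lo + 1`` bins holding the intensity at each
    integer m/z (zero where no peak falls), divided by the maximum intensity
    within the window.  A spectrum with no peaks in the window stays all
    zero.  Non-integer m/z values are rounded to the nearest integer with a
    warning when ``round_mz`` is set, otherwise rejected.
    """
    if lo >= hi:
        raise ValueError("lo must be below hi")
    grid = np.arange(lo, hi + 1, dtype=float)
    values = np.zeros(grid.size)
    if len(peaks) > 0:
        pos = peaks.positions
        rounded = np.rint(pos)
        if not np.allclose(pos, rounded):
            if not round_mz:
                raise ValueError("mass spectrum m/z values must be integers")
            warnings.warn(
                "non-integer m/z values rounded to nearest integer",
                UserWarning,
                stacklevel=2,
            )
        mz = rounded.astype(int)
        for m, inten in zip(mz, peaks.intensities):
            if lo <= m <= hi:
                # summed, not overwritten, if two peaks round to one bin
                values[m - lo] += inten
        mx = values.max()
        if mx > 0:
            values = values / mx
    return SpectrumVector(values, "MS", grid)


def smiles_to_fingerprint(smiles: str, n_bits: int = 1024) -> np.ndarray:
    """Path-based (Daylight-style) binary fingerprint of a SMILES string.

    Deterministic and invariant to the SMILES spelling of a molecule
    (RDKit fingerprints the molecular graph, not the string).

    Raises
    ------
    ValueError
        If the SMILES cannot be parsed, naming the offending string.
    """
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.int8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def fuse_features(blocks: list[np.ndarray]) -> tuple[np.ndarray, list[slice]]:
    """Concatenate feature blocks column-wise (multimodal fusion).

    Returns the fused matrix and the column slice of each input block so the
    provenance of every fused column stays recoverable.
    """
    if not blocks:
        raise ValueError("no feature blocks to fuse")
    blocks = [np.asarray(b, dtype=float) for b in blocks]
    n = blocks[0].shape[0]
    for i, b in enumerate(blocks):
        if b.ndim != 2:
            raise ValueError(f"block {i} is not a 2-D matrix")
        if b.shape[0] != n:
            raise ValueError(
                f"block {i} has {b.shape[0]} rows, expected {n}"
            )
    slices = []
    start = 0
    for b in blocks:
        slices.append(slice(start, start + b.shape[1]))
        start += b.shape[1]
    return np.hstack(blocks), slices
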