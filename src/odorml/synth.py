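"""Synthetic multi-label odor datasets with controlled imbalance.

Real odor datasets pair a few thousand molecules with ~100 odor descriptors
whose frequencies are heavily long-tailed: the most common descriptor
("fruity"-like) covers roughly a quarter of the molecules while the rarest
cover under 1%, and each molecule carries about three descriptors on
average.  This module generates datasets with exactly that statistical
structure, plus a *planted* feature-label signal — each label owns a fixed
set of diagnostic vibrational peaks, mass fragments and fingerprint bits
that appear in a molecule's spectra with a controlled probability when the
label is present — so every downstream stage (featurization, resampling,
classification, attribution) can be tested for recovery of known ground
truth without any external download.

Randomness is governed by a single seed; independent child streams are
spawned in a fixed, documented order (label matrix, diagnostic positions,
per-molecule spectra, fingerprints, SMILES assignment), so regenerating any
stage is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .featurize import PeakList, SmoothingConfig

__all__ = [
    "SynthConfig",
    "SyntheticStudy",
    "SMILES_VOCABULARY",
    "marginal_frequencies",
    "generate_label_matrix",
    "generate_spectra",
    "generate_fingerprints",
    "generate_study",
    "truth_vs_bins",
    "truth_ms_bins",
]

# ~50 small, valid odorant-like molecules (esters, terpenes, alcohols,
# aldehydes, pyrazines ...) reused with replacement; the planted signal for
# recovery tests comes from the peak/bit generators, not from chemistry.
SMILES_VOCABULARY: list[str] = [
    "CCO",                       # ethanol
    "CC(=O)OCC",                 # ethyl acetate
    "CCCC(=O)OCC",               # ethyl butyrate
    "CC(=O)OCC(C)C",             # isobutyl acetate
    "CCCCCC(=O)OCC",             # ethyl hexanoate
    "CC1=CCC(CC1)C(C)C",         # p-menthene-ish terpene
    "CC1=CC[C@@H](CC1)C(=C)C",   # limonene
    "CC(C)=CCCC(C)=CC=O",        # citral
    "CC(C)=CCCC(C)(O)C=C",       # linalool
    "OCC1=CC=CC=C1",             # benzyl alcohol
    "O=CC1=CC=CC=C1",            # benzaldehyde
    "COC1=CC=CC=C1",             # anisole
    "CC(=O)C1=CC=CC=C1",         # acetophenone
    "O=C(OC)C1=CC=CC=C1",        # methyl benzoate
    "CCCCCO",                    # pentanol
    "CCCCCC=O",                  # hexanal
    "CCCCCCCC=O",                # octanal
    "CCCCCCCCC=O",               # nonanal
    "CC(C)CC=O",                 # isovaleraldehyde
    "CCC(C)O",                   # 2-butanol
    "CCCCC(=O)C",                # 2-heptanone
    "CCCCCCC(=O)C",              # 2-nonanone
    "CCCC(=O)CCC",               # 4-heptanone
    "CC1=NC=CN=C1C",             # dimethylpyrazine
    "CCC1=NC=CN=C1",             # ethylpyrazine
    "CC1=CC=C(C=C1)O",           # p-cresol
    "COC1=CC=C(C=C1)C=O",        # anisaldehyde
    "COC1=CC(=CC=C1O)C=O",       # vanillin
    "CC(=O)OC1=CC=CC=C1",        # phenyl acetate
    "OCCC1=CC=CC=C1",            # phenethyl alcohol
    "CC(=O)OCCC1=CC=CC=C1",      # phenethyl acetate
    "C=CCSSCC=C",                # diallyl disulfide
    "CCSC",                      # ethyl methyl sulfide
    "CCCCS",                     # butanethiol
    "O=C1CCCCC1",                # cyclohexanone
    "OC1CCCCC1",                 # cyclohexanol
    "CC1CCC(C(C)C)C(O)C1",       # menthol-like
    "CC1=CCC2CC1C2(C)C",         # pinene
    "CC(=O)CC(C)C",              # methyl isobutyl ketone
    "CCOC(=O)C(C)C",             # ethyl isobutyrate
    "CCOC(=O)CC(C)C",            # ethyl isovalerate
    "CCCCOC(=O)C",               # butyl acetate
    "CCCCCOC(=O)C",              # amyl acetate
    "CCCCCCO",                   # hexanol
    "C=CCC1=CC=C(OC)C=C1",       # estragole
    "COC1=CC=C(C=C1)CC=C",       # methyl chavicol variant
    "O=C(C)CCC1=CC=CC=C1",       # benzylacetone
    "CC(C)CCO",                  # isoamyl alcohol
    "CC(C)CCOC(=O)C",            # isoamyl acetate
    "O=CC=CC1=CC=CC=C1",         # cinnamaldehyde
]

# intensity ranges: diagnostic peaks are strong modes, noise peaks weaker
# background; both in arbitrary units (only ratios survive normalisation)
_SIGNAL_INTENSITY = (0.5, 1.0)
_NOISE_INTENSITY = (0.1, 0.5)

_VS_RANGE = (1.0, 4000.0)
_MS_RANGE = (50, 262)
_FP_BITS = 1024


@dataclass
class SynthConfig:
    """Study conditions for a synthetic odor dataset.

    Defaults emulate the published odor-descriptor statistics: ~2600
    molecules, 109 labels, the most frequent label on ~27% of molecules,
    the rarest on ~1%, and a label cardinality of ~3.16 labels/molecule.
    """

    n_molecules: int = 2606
    n_labels: int = 109
    cardinality_target: float = 3.16
    head_frequency: float = 0.27
    tail_frequency: float = 0.01
    signal_strength: float = 0.9
    noise_peaks: int = 3
    vs_peaks_per_label: int = 3
    ms_peaks_per_label: int = 2
    fp_bits_per_label: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules <= 0 or self.n_labels <= 0:
            raise ValueError("counts must be positive")
        if not (0 < self.tail_frequency <= self.head_frequency <= 1):
            raise ValueError("need 0 < tail_frequency <= head_frequency <= 1")
        if self.cardinality_target < 1:
            raise ValueError("cardinality_target must be >= 1")
        if self.cardinality_target > self.n_labels:
            raise ValueError(
                f"cardinality_target={self.cardinality_target} exceeds "
                f"n_labels={self.n_labels}: infeasible"
            )
        if not (0 <= self.signal_strength <= 1):
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.noise_peaks < 0:
            raise ValueError("noise_peaks must be >= 0")


@dataclass
class SyntheticStudy:
    """One generated dataset: molecules, spectra, labels and planted truth."""

    smiles: list[str]
    vs_peaks: list[PeakList]
    ms_peaks: list[PeakList]
    fingerprints: np.ndarray
    labels: np.ndarray
    label_names: list[str]
    truth: dict[int, dict[str, np.ndarray]]
    config: SynthConfig = field(repr=False, default=None)


def marginal_frequencies(cfg: SynthConfig) -> np.ndarray:
    """Target per-label frequencies: warped geometric decay head -> tail.

    Frequencies follow ``f_l = head * (tail/head) ** ((l / (L-1)) ** beta)``
    so the first label sits exactly at ``head_frequency`` and the last at
    ``tail_frequency``.  The shape exponent ``beta`` is calibrated by root
    finding so that the expected cardinality *conditional on at least one
    label* (empty draws are rejected at sampling time) matches
    ``cardinality_target``.  A pure geometric decay (beta = 1) cannot in
    general satisfy head, tail and cardinality simultaneously.
    """
    L = cfg.n_labels
    head, tail = cfg.head_frequency, cfg.tail_frequency
    if L == 1:
        return np.array([head])
    if head == tail:
        f = np.full(L, head)
        if not np.isclose(_conditional_card(f), cfg.cardinality_target, rtol=0.1):
            raise ValueError(
                "head == tail fixes the cardinality at "
                f"{_conditional_card(f):.3f}, incompatible with "
                f"cardinality_target={cfg.cardinality_target}"
            )
        return f

    t = np.arange(L) / (L - 1)
    log_ratio = np.log(tail / head)

    def freqs(beta: float) -> np.ndarray:
        return head * np.exp(log_ratio * t**beta)

    def gap(beta: float) -> float:
        return _conditional_card(freqs(beta)) - cfg.cardinality_target

    # beta -> 0: all interior labels at tail (minimal card);
    # beta -> inf: all interior labels at head (maximal card)
    lo, hi = 1e-3, 1e3
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"cardinality_target={cfg.cardinality_target} unreachable with "
            f"head={head}, tail={tail}, n_labels={L} "
            f"(achievable range [{_conditional_card(freqs(lo)):.3f}, "
            f"{_conditional_card(freqs(hi)):.3f}])"
        )
    beta = brentq(gap, lo, hi, xtol=1e-10)
    return freqs(beta)


def _conditional_card(f: np.ndarray) -> float:
    """E[number of labels | >= 1 label] for independent Bernoulli marginals."""
    p_empty = np.prod(1.0 - f)
    return float(f.sum() / (1.0 - p_empty)) if p_empty < 1 else np.inf


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def generate_label_matrix(cfg: SynthConfig) -> np.ndarray:
    """Sample an (n_molecules, n_labels) binary matrix with long-tail marginals.

    Labels are drawn independently per molecule from the calibrated
    marginals; all-zero rows are redrawn so every molecule carries at least
    one label.  Columns are then re-ordered by empirical positive count so
    marginal frequencies are non-increasing in design rank.  Deterministic
    given ``cfg.seed``.
    """
    f = marginal_frequencies(cfg)
    rng = _child_rngs(cfg.seed, 5)[0]
    Y = (rng.random((cfg.n_molecules, cfg.n_labels)) < f).astype(np.int8)
    empty = np.flatnonzero(Y.sum(axis=1) == 0)
    guard = 0
    while empty.size and guard < 1000:
        Y[empty] = (rng.random((empty.size, cfg.n_labels)) < f).astype(np.int8)
        empty = empty[Y[empty].sum(axis=1) == 0]
        guard += 1
    if empty.size:  # pathological config; force the head label on
        Y[empty, 0] = 1
    order = np.argsort(-Y.sum(axis=0), kind="stable")
    return np.ascontiguousarray(Y[:, order])


def _diagnostic_positions(cfg: SynthConfig, rng: np.random.Generator):
    """Fixed per-label diagnostic VS/MS positions (label index -> positions)."""
    # VS candidates on a 10 cm^-1 lattice keep labels' peaks distinguishable
    vs_candidates = np.arange(100.0, 3990.0, 10.0)
    n_vs = cfg.n_labels * cfg.vs_peaks_per_label
    vs_all = rng.choice(
        vs_candidates, size=n_vs, replace=n_vs > vs_candidates.size
    )
    ms_candidates = np.arange(_MS_RANGE[0], _MS_RANGE[1] + 1)
    n_ms = cfg.n_labels * cfg.ms_peaks_per_label
    ms_all = rng.choice(
        ms_candidates, size=n_ms, replace=n_ms > ms_candidates.size
    )
    vs = {
        lab: vs_all[lab * cfg.vs_peaks_per_label : (lab + 1) * cfg.vs_peaks_per_label]
        for lab in range(cfg.n_labels)
    }
    ms = {
        lab: ms_all[lab * cfg.ms_peaks_per_label : (lab + 1) * cfg.ms_peaks_per_label].astype(float)
        for lab in range(cfg.n_labels)
    }
    return vs, ms


def generate_spectra(
    labels: np.ndarray, cfg: SynthConfig
) -> tuple[list[PeakList], list[PeakList], dict[int, dict[str, np.ndarray]]]:
    """Planted-signal VS and MS peak lists for each molecule.

    Each label owns fixed diagnostic wavenumbers (within [1, 4000] cm^-1)
    and integer m/z fragments (within [50, 262]).  A molecule carrying a
    label includes each of that label's diagnostic peaks independently with
    probability ``signal_strength``; ``noise_peaks`` uniformly random peaks
    are added to both spectra.  Returns the peak lists and a ``truth`` dict
    mapping label index -> {"vs": positions, "ms": positions}.
    """
    labels = np.asarray(labels)
    rngs = _child_rngs(cfg.seed, 5)
    diag_rng, mol_rng = rngs[1], rngs[2]
    vs_diag, ms_diag = _diagnostic_positions(cfg, diag_rng)

    vs_peaks: list[PeakList] = []
    ms_peaks: list[PeakList] = []
    for i in range(labels.shape[0]):
        own = np.flatnonzero(labels[i])
        vs_pos, vs_int, ms_pos, ms_int = [], [], [], []
        for lab in own:
            for p in vs_diag[lab]:
                if mol_rng.random() < cfg.signal_strength:
                    vs_pos.append(p)
                    vs_int.append(mol_rng.uniform(*_SIGNAL_INTENSITY))
            for p in ms_diag[lab]:
                if mol_rng.random() < cfg.signal_strength:
                    ms_pos.append(p)
                    ms_int.append(mol_rng.uniform(*_SIGNAL_INTENSITY))
        for _ in range(cfg.noise_peaks):
            vs_pos.append(mol_rng.uniform(*_VS_RANGE))
            vs_int.append(mol_rng.uniform(*_NOISE_INTENSITY))
            ms_pos.append(float(mol_rng.integers(_MS_RANGE[0], _MS_RANGE[1] + 1)))
            ms_int.append(mol_rng.uniform(*_NOISE_INTENSITY))
        vs_peaks.append(PeakList(np.array(vs_pos), np.array(vs_int)))
        ms_peaks.append(PeakList(np.array(ms_pos), np.array(ms_int)))

    truth = {
        lab: {"vs": vs_diag[lab].copy(), "ms": ms_diag[lab].copy()}
        for lab in range(cfg.n_labels)
    }
    return vs_peaks, ms_peaks, truth


def generate_fingerprints(
    labels: np.ndarray, cfg: SynthConfig
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Planted-bit binary fingerprints (n_molecules x 1024).

    Each label owns ``fp_bits_per_label`` diagnostic bits; a molecule
    carrying the label sets each bit with probability ``signal_strength``;
    ``noise_peaks`` random extra bits are set per molecule.  Returns the bit
    matrix and the per-label diagnostic bit indices.
    """
    labels = np.asarray(labels)
    rngs = _child_rngs(cfg.seed, 5)
    diag_rng, mol_rng = rngs[1], rngs[3]
    n_bits_needed = cfg.n_labels * cfg.fp_bits_per_label
    all_bits = diag_rng.choice(
        _FP_BITS, size=n_bits_needed, replace=n_bits_needed > _FP_BITS
    )
    bit_map = {
        lab: np.sort(
            all_bits[lab * cfg.fp_bits_per_label : (lab + 1) * cfg.fp_bits_per_label]
        )
        for lab in range(cfg.n_labels)
    }
    fp = np.zeros((labels.shape[0], _FP_BITS), dtype=np.int8)
    for i in range(labels.shape[0]):
        for lab in np.flatnonzero(labels[i]):
            mask = mol_rng.random(cfg.fp_bits_per_label) < cfg.signal_strength
            fp[i, bit_map[lab][mask]] = 1
        if cfg.noise_peaks:
            fp[i, mol_rng.integers(0, _FP_BITS, size=cfg.noise_peaks)] = 1
    return fp, bit_map


def generate_study(cfg: SynthConfig) -> SyntheticStudy:
    """Generate a complete synthetic study: labels, spectra, fingerprints.

    Truth holds, per label index, the diagnostic "vs" wavenumbers, "ms"
    fragments and "fp" bit indices used to plant the signal.
    """
    Y = generate_label_matrix(cfg)
    vs_peaks, ms_peaks, truth = generate_spectra(Y, cfg)
    fp, bit_map = generate_fingerprints(Y, cfg)
    for lab in truth:
        truth[lab]["fp"] = bit_map[lab]
    smiles_rng = _child_rngs(cfg.seed, 5)[4]
    smiles = [
        SMILES_VOCABULARY[k]
        for k in smiles_rng.integers(0, len(SMILES_VOCABULARY), cfg.n_molecules)
    ]
    names = [f"odor_{j:03d}" for j in range(cfg.n_labels)]
    return SyntheticStudy(
        smiles=smiles,
        vs_peaks=vs_peaks,
        ms_peaks=ms_peaks,
        fingerprints=fp,
        labels=Y,
        label_names=names,
        truth=truth,
        config=cfg,
    )


def truth_vs_bins(
    truth: dict[int, dict[str, np.ndarray]],
    smoothing: SmoothingConfig | None = None,
) -> dict[int, np.ndarray]:
    """Map each label's diagnostic wavenumbers to nearest BFS grid indices."""
    smoothing = smoothing or SmoothingConfig()
    grid = smoothing.grid
    out = {}
    for lab, d in truth.items():
        idx = np.abs(grid[None, :] - d["vs"][:, None]).argmin(axis=1)
        out[lab] = np.unique(idx)
    return out


def truth_ms_bins(
    truth: dict[int, dict[str, np.ndarray]], lo: int = 50, hi: int = 262
) -> dict[int, np.ndarray]:
    """Map each label's diagnostic m/z fragments to window bin indices."""
    out = {}
    for lab, d in truth.items():
        mz = d["ms"].astype(int)
        out[lab] = np.unique(mz[(mz >= lo) & (mz <= hi)] - lo)
    return out


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write a study to disk as plain-text CSV/JSON (labels, peak lists,
    fingerprints, truth)."""
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    (outdir / "vs").mkdir(parents=True, exist_ok=True)
    (outdir / "ms").mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        study.labels,
        columns=study.label_names,
        index=[f"mol_{i}" for i in range(len(study.smiles))],
    ).to_csv(outdir / "labels.csv")
    pd.DataFrame(study.fingerprints).to_csv(outdir / "fingerprints.csv", index=False)
    (outdir / "smiles.txt").write_text("\n".join(study.smiles) + "\n")
    for i, (vp, mp) in enumerate(zip(study.vs_peaks, study.ms_peaks)):
        pd.DataFrame(
            {"position": vp.positions, "intensity": vp.intensities}
        ).to_csv(outdir / "vs" / f"mol_{i}.csv", index=False)
        pd.DataFrame(
            {"position": mp.positions, "intensity": mp.intensities}
        ).to_csv(outdir / "ms" / f"mol_{i}.csv", index=False)
    truth_json = {
        str(lab): {k: v.tolist() for k, v in d.items()}
        for lab, d in study.truth.items()
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1))
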