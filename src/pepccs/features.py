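"""Sequence featurization: per-residue descriptors, cumulative window
features, the fixed-length 323-channel spatial encoding for the convolutional
branch, and the multi-scale global feature vector for the dense branch.

Per-residue feature vector (45 entries)
---------------------------------------
==  =========================================================================
0-20   one-hot residue identity (oxidized Met is index 20)
21-25  elemental composition of the residue: H, C, N, O, S counts
26-35  side-chain class flags: acidic, modified (non-standard), amide,
       non-polar, small, uncharged polar, aliphatic non-polar, aromatic,
       positively charged, hydroxyl
36     1 for N or D, else 0
37     1 for E or Q, else 0
38-43  six float literature descriptor scales
44     padding flag: 0 for every residue, 1 only for padding positions
==  =========================================================================

Cumulative features over a window ``w = [j_start, j_end]`` (inclusive):

* ``C1``: sum of F over the window, divided by 100 (keeps magnitudes small),
* ``C2``: window sum divided by the full-sequence sum (0 when the feature is
  absent from the whole peptide),
* ``C3``: window mean (sum divided by the window length).

Spatial encoding (L x 323 per peptide)
--------------------------------------
Channel 0: residue indicator (1 for residues, 0 for padding); channels 1-3:
N-terminus / acetylated-N-terminus / C-terminus flags; channels 4-318: the
315-entry block F, C1/C2/C3 of the prefix [0, j], C1/C2/C3 of the suffix
[j, n-1] (seven 45-wide sub-blocks); channel 319: relative position
j/(n-1); channels 320/321: residue distance from the N-/C-terminus;
channel 322: charge state, replicated over every position including padding.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .chemistry import Peptide, Residue, ResidueChemistryTable, default_chemistry
from .errors import EncodingLengthError

N_RESIDUE_FEATURES = 45
PAD_FEATURE = 44
CUMULATIVE_BLOCK = 7 * N_RESIDUE_FEATURES  # F + 3 prefix + 3 suffix sets = 315
SPATIAL_CHANNELS = 4 + CUMULATIVE_BLOCK + 3 + 1  # = 323
N_GLOBAL_SCALARS = 6

# channel anchors within the spatial encoding
CH_RESIDUE = 0
CH_NTERM = 1
CH_ACETYL = 2
CH_CTERM = 3
CH_FBLOCK = 4
CH_RELPOS = 319
CH_DIST_N = 320
CH_DIST_C = 321
CH_CHARGE = 322

LAYOUT_VERSION = 1


def residue_features(r: Residue, chem: ResidueChemistryTable | None = None) -> np.ndarray:
    """The 45-entry descriptor vector for one residue."""
    chem = chem or default_chemistry()
    e = chem[r.symbol]
    v = np.zeros(N_RESIDUE_FEATURES)
    v[e.one_hot_index] = 1.0
    v[21:26] = e.composition.as_tuple()
    v[26:36] = e.class_flags
    v[36:38] = e.dyad_flags
    v[38:44] = e.descriptors
    # v[44] stays 0: the padding flag is never set for a real residue
    return v


def padding_features() -> np.ndarray:
    """Descriptor vector of the padding symbol: all zero except the pad flag."""
    v = np.zeros(N_RESIDUE_FEATURES)
    v[PAD_FEATURE] = 1.0
    return v


def feature_matrix(p: Peptide, chem: ResidueChemistryTable | None = None) -> np.ndarray:
    """n x 45 matrix with row j = residue_features(residue j)."""
    chem = chem or default_chemistry()
    return np.stack([residue_features(r, chem) for r in p.residues])


@dataclass(frozen=True)
class Window:
    """Inclusive 0-based residue index range [j_start, j_end]."""

    j_start: int
    j_end: int

    def __post_init__(self) -> None:
        if not 0 <= self.j_start <= self.j_end:
            raise ValueError(f"invalid window [{self.j_start}, {self.j_end}]")

    @property
    def length(self) -> int:
        return self.j_end - self.j_start + 1


def cumulative(F: np.ndarray, kind: int, w: Window) -> np.ndarray:
    """Cumulative feature vector of one kind over a window of ``F``.

    kind 1: window sum / 100; kind 2: window sum / full-sequence sum (0 where
    the full sum is 0); kind 3: window mean.
    """
    n = F.shape[0]
    if w.j_end >= n:
        raise ValueError(f"window [{w.j_start}, {w.j_end}] out of bounds for n={n}")
    seg = F[w.j_start : w.j_end + 1].sum(axis=0)
    if kind == 1:
        return seg / 100.0
    if kind == 2:
        total = F.sum(axis=0)
        out = np.zeros_like(seg)
        nz = total != 0
        out[nz] = seg[nz] / total[nz]
        return out
    if kind == 3:
        return seg / w.length
    raise ValueError(f"cumulative kind must be 1, 2 or 3, got {kind}")


def spatial_encoding(
    p: Peptide,
    L: int = 96,
    chem: ResidueChemistryTable | None = None,
) -> np.ndarray:
    """Fixed-length L x 323 multi-channel encoding for the conv branch."""
    chem = chem or default_chemistry()
    n = len(p)
    if L < n + 41:
        raise EncodingLengthError(
            f"encoding length {L} too short for n={n} (need >= n + 41)"
        )
    F = feature_matrix(p, chem)
    prefix = np.cumsum(F, axis=0)  # prefix[j] = sum over [0, j]
    total = prefix[-1]
    suffix = total[None, :] - prefix + F  # suffix[j] = sum over [j, n-1]

    inv_total = np.zeros_like(total)
    nz = total != 0
    inv_total[nz] = 1.0 / total[nz]
    j = np.arange(n)
    pre_len = (j + 1)[:, None].astype(float)
    suf_len = (n - j)[:, None].astype(float)

    M = np.zeros((L, SPATIAL_CHANNELS))
    M[:n, CH_RESIDUE] = 1.0
    M[0, CH_NTERM] = 1.0
    if p.n_term_acetylated:
        M[0, CH_ACETYL] = 1.0
    M[n - 1, CH_CTERM] = 1.0

    k = N_RESIDUE_FEATURES
    blocks = (
        F,  # F(i, j)
        prefix / 100.0,  # C1(0, j)
        prefix * inv_total[None, :],  # C2(0, j)
        prefix / pre_len,  # C3(0, j)
        suffix / 100.0,  # C1(j, n-1)
        suffix * inv_total[None, :],  # C2(j, n-1)
        suffix / suf_len,  # C3(j, n-1)
    )
    for b, block in enumerate(blocks):
        M[:n, CH_FBLOCK + b * k : CH_FBLOCK + (b + 1) * k] = block
    # padding rows carry the padding symbol in the F sub-block
    M[n:, CH_FBLOCK + PAD_FEATURE] = 1.0

    M[:n, CH_RELPOS] = j / (n - 1) if n > 1 else 0.0
    M[:n, CH_DIST_N] = j
    M[:n, CH_DIST_C] = n - 1 - j
    M[:, CH_CHARGE] = p.charge
    return M


@dataclass(frozen=True)
class SubsequenceLayoutConfig:
    """Which subsequences feed windowed C1 features to the dense branch.

    ``fixed_lengths``: window sizes anchored at both termini (clamped when the
    peptide is shorter).  ``fractional_levels``: numbers of consecutive
    windows tiling the peptide (2, 4, 8, 16 correspond to window lengths of
    1/2 ... 1/16 of the peptide); borders are rounded half-up and repaired so
    every window keeps at least one residue.
    """

    fixed_lengths: tuple[int, ...] = (5, 10, 20)
    fractional_levels: tuple[int, ...] = (2, 4, 8, 16)

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.fixed_lengths + self.fractional_levels):
            raise ValueError("all window lengths/levels must be >= 1")

    @property
    def n_windows(self) -> int:
        return 2 * len(self.fixed_lengths) + sum(self.fractional_levels)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _fractional_windows(n: int, k: int) -> list[Window]:
    """k consecutive windows covering [0, n-1]; a tiling when n >= k."""
    bounds = [_round_half_up(t * n / k) for t in range(k + 1)]
    bounds[0], bounds[k] = 0, n
    if n >= k:
        for t in range(1, k):
            b = max(bounds[t], bounds[t - 1] + 1)  # keep >= 1 residue per window
            bounds[t] = min(b, n - (k - t))  # leave room for the rest
    windows = []
    for t in range(k):
        s = min(bounds[t], n - 1)
        e = min(max(bounds[t + 1] - 1, s), n - 1)
        windows.append(Window(s, e))
    return windows


def subsequence_windows(n: int, cfg: SubsequenceLayoutConfig | None = None) -> list[Window]:
    """Ordered window layout; the count depends only on the config, not on n.

    Order: for each fixed length k the N-terminal then the C-terminal window,
    then each fractional level's windows left to right.
    """
    if n < 1:
        raise ValueError("peptide length must be >= 1")
    cfg = cfg or SubsequenceLayoutConfig()
    windows: list[Window] = []
    for k in cfg.fixed_lengths:
        windows.append(Window(0, min(k, n) - 1))
        windows.append(Window(max(0, n - k), n - 1))
    for level in cfg.fractional_levels:
        windows.extend(_fractional_windows(n, level))
    return windows


def global_features(
    p: Peptide,
    cfg: SubsequenceLayoutConfig | None = None,
    reduced: bool = False,
    chem: ResidueChemistryTable | None = None,
) -> np.ndarray:
    """Dense-branch input: 6 scalars, plus windowed C1 features unless reduced.

    Scalars: peptide length, charge, one-hot charge (2/3/4), acetylation flag.
    """
    cfg = cfg or SubsequenceLayoutConfig()
    chem = chem or default_chemistry()
    n = len(p)
    scalars = np.array(
        [
            float(n),
            float(p.charge),
            1.0 if p.charge == 2 else 0.0,
            1.0 if p.charge == 3 else 0.0,
            1.0 if p.charge == 4 else 0.0,
            1.0 if p.n_term_acetylated else 0.0,
        ]
    )
    if reduced:
        return scalars
    F = feature_matrix(p, chem)
    parts = [scalars]
    for w in subsequence_windows(n, cfg):
        parts.append(cumulative(F, 1, w))
    return np.concatenate(parts)


def global_length(cfg: SubsequenceLayoutConfig | None = None, reduced: bool = False) -> int:
    cfg = cfg or SubsequenceLayoutConfig()
    if reduced:
        return N_GLOBAL_SCALARS
    return N_GLOBAL_SCALARS + N_RESIDUE_FEATURES * cfg.n_windows


@dataclass(frozen=True)
class FeaturizationConfig:
    """Everything that determines the encoded tensors for a peptide."""

    L: int = 96
    layout: SubsequenceLayoutConfig = field(default_factory=SubsequenceLayoutConfig)
    reduced: bool = False

    @property
    def global_dim(self) -> int:
        return global_length(self.layout, self.reduced)


def featurization_hash(
    cfg: FeaturizationConfig, chem: ResidueChemistryTable | None = None
) -> str:
    """Stable hash binding a model to the featurization that trained it."""
    chem = chem or default_chemistry()
    payload = json.dumps(
        {
            "layout_version": LAYOUT_VERSION,
            "L": cfg.L,
            "fixed_lengths": list(cfg.layout.fixed_lengths),
            "fractional_levels": list(cfg.layout.fractional_levels),
            "reduced": cfg.reduced,
            "chemistry": chem.content_key(),
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class EncodedDataset:
    """Featurized peptides ready for the network.

    ``spatial``: (B, L, 323) float32; ``glob``: (B, G) float32;
    ``ccs``: optional (B,) reference CCS in Angstrom^2.
    """

    spatial: np.ndarray
    glob: np.ndarray
    config: FeaturizationConfig
    feature_hash: str
    ccs: np.ndarray | None = None
    charges: np.ndarray | None = None

    def __len__(self) -> int:
        return self.spatial.shape[0]


def encode_peptides(
    peptides: list[Peptide],
    cfg: FeaturizationConfig | None = None,
    ccs: np.ndarray | None = None,
    chem: ResidueChemistryTable | None = None,
) -> EncodedDataset:
    """Encode a peptide list into spatial and global tensors."""
    cfg = cfg or FeaturizationConfig()
    chem = chem or default_chemistry()
    B = len(peptides)
    spatial = np.empty((B, cfg.L, SPATIAL_CHANNELS), dtype=np.float32)
    glob = np.empty((B, cfg.global_dim), dtype=np.float32)
    for b, p in enumerate(peptides):
        spatial[b] = spatial_encoding(p, cfg.L, chem)
        glob[b] = global_features(p, cfg.layout, cfg.reduced, chem)
    return EncodedDataset(
        spatial=spatial,
        glob=glob,
        config=cfg,
        feature_hash=featurization_hash(cfg, chem),
        ccs=None if ccs is None else np.asarray(ccs, dtype=np.float64),
        charges=np.array([p.charge for p in peptides]),
    )


def layout_manifest(cfg: FeaturizationConfig | None = None) -> dict[str, object]:
    """Machine-readable channel map for exported encodings."""
    cfg = cfg or FeaturizationConfig()
    blocks = ["F", "C1_prefix", "C2_prefix", "C3_prefix", "C1_suffix", "C2_suffix", "C3_suffix"]
    channels: dict[int, str] = {
        CH_RESIDUE: "residue_indicator",
        CH_NTERM: "n_terminus",
        CH_ACETYL: "acetylated_n_terminus",
        CH_CTERM: "c_terminus",
        CH_RELPOS: "relative_position",
        CH_DIST_N: "distance_from_n_terminus",
        CH_DIST_C: "distance_from_c_terminus",
        CH_CHARGE: "charge_state",
    }
    for b, name in enumerate(blocks):
        for i in range(N_RESIDUE_FEATURES):
            channels[CH_FBLOCK + b * N_RESIDUE_FEATURES + i] = f"{name}[{i}]"
    return {
        "layout_version": LAYOUT_VERSION,
        "L": cfg.L,
        "spatial_channels": {str(k): channels[k] for k in sorted(channels)},
        "global_dim": cfg.global_dim,
        "reduced": cfg.reduced,
        "fixed_lengths": list(cfg.layout.fixed_lengths),
        "fractional_levels": list(cfg.layout.fractional_levels),
    }
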