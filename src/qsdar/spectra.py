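"""Fixed-length spectral descriptor encodings of NMR peak lists.

Three encodings are provided:

* ``spinus570`` — 285 uniform bins over the ¹H chemical-shift axis plus 285
  uniform bins over the scalar-coupling axis, emulating the shape of codes
  produced from feed-forward-network shift/coupling predictors;
* ``gnn250`` — five atom-type channels (H, C, N, O, other) of 50 shift bins
  each, emulating multi-nucleus graph-network shift predictors;
* ``combo820`` — the concatenation, 570-code first.

Bin edges and widths are configuration, not physics: the code lengths are the
contract, and the default grids cover the standard ¹H shift (−1 to 13 ppm) and
J-coupling (0 to 28 Hz) ranges with uniform bins.  Intensities are weighted by
nucleus count so integration information survives the binning; couplings count
once per listed peak.  Out-of-range values are accumulated in the nearest
terminal bin (with a warning) rather than dropped, so total mass is conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Peak",
    "PeakList",
    "SpectralVector",
    "BinScheme",
    "SPINUS_SHIFT_BINS",
    "SPINUS_COUPLING_BINS",
    "GNN_CHANNELS",
    "encode_spinus570",
    "encode_gnn250",
    "concat_spectra",
    "encode",
]


@dataclass(frozen=True)
class Peak:
    """A single resonance: chemical shift, couplings and nucleus count."""

    shift: float  # ppm
    couplings: tuple[float, ...] = ()  # Hz, all >= 0
    n_protons: int = 1  # nucleus count (integration)
    atom_type: str = "H"

    def __post_init__(self):
        if not np.isfinite(self.shift):
            raise ValueError(f"non-finite chemical shift: {self.shift}")
        if self.n_protons < 1:
            raise ValueError(f"n_protons must be >= 1, got {self.n_protons}")
        if any(j < 0 or not np.isfinite(j) for j in self.couplings):
            raise ValueError(f"couplings must be finite and >= 0 Hz: {self.couplings}")


@dataclass(frozen=True)
class PeakList:
    """An (unordered) list of peaks for one molecule."""

    molecule_id: str
    peaks: tuple[Peak, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "peaks", tuple(self.peaks))

    @property
    def total_protons(self) -> int:
        return sum(p.n_protons for p in self.peaks if p.atom_type == "H")


@dataclass(frozen=True)
class SpectralVector:
    encoding_id: str  # spinus570 | gnn250 | combo820
    values: np.ndarray  # fixed length, all >= 0
    bin_edges: dict = field(default_factory=dict, compare=False)

    _LENGTHS = {"spinus570": 570, "gnn250": 250, "combo820": 820}

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        expected = self._LENGTHS.get(self.encoding_id)
        if expected is None:
            raise ValueError(f"unknown encoding_id: {self.encoding_id!r}")
        if self.values.shape != (expected,):
            raise ValueError(
                f"{self.encoding_id} vector must have length {expected}, "
                f"got shape {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("spectral descriptor values must be non-negative")


@dataclass(frozen=True)
class BinScheme:
    """Uniform binning of a half-open interval [lo, hi) into n bins."""

    lo: float
    hi: float
    n: int

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.n

    def index(self, x: float) -> tuple[int, bool]:
        """Bin index for x; second element flags an out-of-range clip."""
        i = int(np.floor((x - self.lo) / self.width))
        if i < 0:
            return 0, True
        if i >= self.n:
            return self.n - 1, True
        return i, False

    def edges(self) -> np.ndarray:
        return self.lo + self.width * np.arange(self.n + 1)


# 285 shift bins at 0.05 ppm + 285 coupling bins at 0.1 Hz = 570 descriptors.
SPINUS_SHIFT_BINS = BinScheme(-1.0, 13.25, 285)
SPINUS_COUPLING_BINS = BinScheme(0.0, 28.5, 285)

# Five atom-type channels x 50 shift bins = 250 descriptors.  Shift ranges are
# per-element; elements outside H/C/N/O fall into the catch-all channel.
GNN_CHANNELS: dict[str, BinScheme] = {
    "H": BinScheme(-1.0, 14.0, 50),
    "C": BinScheme(0.0, 250.0, 50),
    "N": BinScheme(0.0, 500.0, 50),
    "O": BinScheme(0.0, 500.0, 50),
    "other": BinScheme(-50.0, 450.0, 50),
}
_GNN_ORDER = ("H", "C", "N", "O", "other")


def _accumulate(scheme: BinScheme, values, weights, out: np.ndarray, what: str):
    clipped = 0
    for x, w in zip(values, weights):
        i, oob = scheme.index(x)
        out[i] += w
        clipped += oob
    if clipped:
        warnings.warn(
            f"{clipped} {what} value(s) outside [{scheme.lo}, {scheme.hi}) "
            "accumulated in the terminal bin", stacklevel=3)


def encode_spinus570(peaks: PeakList,
                     shift_bins: BinScheme = SPINUS_SHIFT_BINS,
                     coupling_bins: BinScheme = SPINUS_COUPLING_BINS) -> SpectralVector:
    """Encode a ¹H peak list as 285 shift bins + 285 coupling bins.

    Shift bins are weighted by proton count; each coupling constant adds one
    count per peak that lists it.  The sum of the shift half therefore equals
    the total ¹H count of the peak list.
    """
    vec = np.zeros(shift_bins.n + coupling_bins.n)
    h_peaks = [p for p in peaks.peaks if p.atom_type == "H"]
    _accumulate(shift_bins, [p.shift for p in h_peaks],
                [p.n_protons for p in h_peaks], vec[:shift_bins.n], "shift")
    js = [j for p in h_peaks for j in p.couplings]
    _accumulate(coupling_bins, js, [1.0] * len(js), vec[shift_bins.n:], "coupling")
    return SpectralVector(
        "spinus570", vec,
        bin_edges={"shift_ppm": shift_bins.edges(), "coupling_hz": coupling_bins.edges()})


def encode_gnn250(peaks: PeakList,
                  channels: dict[str, BinScheme] | None = None) -> SpectralVector:
    """Encode shifts of any nucleus into 5 atom-type channels x 50 bins."""
    channels = GNN_CHANNELS if channels is None else channels
    per = next(iter(channels.values())).n
    vec = np.zeros(len(_GNN_ORDER) * per)
    for p in peaks.peaks:
        channel = p.atom_type if p.atom_type in channels else "other"
        offset = _GNN_ORDER.index(channel) * per
        i, oob = channels[channel].index(p.shift)
        vec[offset + i] += p.n_protons
        if oob:
            warnings.warn(
                f"shift {p.shift} ppm outside the {channel} channel range; "
                "accumulated in the terminal bin", stacklevel=2)
    return SpectralVector(
        "gnn250", vec,
        bin_edges={ch: channels[ch].edges() for ch in _GNN_ORDER})


def concat_spectra(a: SpectralVector, b: SpectralVector) -> SpectralVector:
    """Concatenate a spinus570 and a gnn250 vector (in that order) into combo820."""
    if (a.encoding_id, b.encoding_id) != ("spinus570", "gnn250"):
        raise ValueError(
            "concat_spectra expects (spinus570, gnn250), got "
            f"({a.encoding_id}, {b.encoding_id})")
    edges = dict(a.bin_edges)
    edges.update({f"gnn_{k}": v for k, v in b.bin_edges.items()})
    return SpectralVector("combo820", np.concatenate([a.values, b.values]), edges)


def encode(peaks: PeakList, encoding_id: str) -> SpectralVector:
    """Dispatch to the encoder named by ``encoding_id``."""
    if encoding_id == "spinus570":
        return encode_spinus570(peaks)
    if encoding_id == "gnn250":
        return encode_gnn250(peaks)
    if encoding_id == "combo820":
        return concat_spectra(encode_spinus570(peaks), encode_gnn250(peaks))
    raise ValueError(f"unknown encoding_id: {encoding_id!r}")
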