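"""Per-base signal tracks and binned contact matrices.

These are the two data containers shared by the simulator (which writes
them) and the chromatin-integration layer (which reads them). Text formats
only: bedGraph for tracks, a dense whitespace-delimited matrix plus a bin
table for contacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeDefinition


@dataclass
class SignalTrack:
    """Nonnegative per-base signal, one float array per chromosome."""

    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"{chrom}: negative signal")
            self.values[chrom] = arr

    def window_mean(
        self, genome: GenomeDefinition, chrom: str, center: int, halfwidth: int
    ) -> float:
        """Mean signal over [center-halfwidth, center+halfwidth), wrapped on
        circular chromosomes and truncated at linear ends."""
        arr = self.values[chrom]
        n = arr.size
        if genome.chromosomes[chrom].circular:
            idx = np.arange(center - halfwidth, center + halfwidth) % n
            return float(arr[idx].mean())
        lo = max(0, center - halfwidth)
        hi = min(n, center + halfwidth)
        return float(arr[lo:hi].mean())

    def to_bedgraph(self, path: str | Path) -> None:
        """Run-length-encoded bedGraph (0-based half-open)."""
        with open(path, "w") as fh:
            for chrom, arr in self.values.items():
                if arr.size == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.6g}\n")

    @classmethod
    def from_bedgraph(cls, path: str | Path, genome: GenomeDefinition) -> "SignalTrack":
        values = {
            name: np.zeros(spec.length) for name, spec in genome.chromosomes.items()
        }
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, s, e, v = line.split()[:4]
                values[chrom][int(s) : int(e)] = float(v)
        return cls(values)


@dataclass
class ContactModel:
    """Symmetric binned contact-probability matrix at fixed resolution.

    ``bins`` has columns (chrom, start, end) in matrix row order; ``C`` is
    the dense symmetric matrix with a positive diagonal.
    """

    bin_size: int
    bins: pd.DataFrame
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape[0] != self.C.shape[1] or len(self.bins) != self.C.shape[0]:
            raise ValueError("bin table and matrix shapes disagree")
        if not np.allclose(self.C, self.C.T):
            raise ValueError("contact matrix must be symmetric")
        if (np.diag(self.C) <= 0).any():
            raise ValueError("contact matrix diagonal must be positive")
        self._offsets = {}
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            self._offsets[chrom] = (int(grp.index.min()), int(grp.index.max()))

    def n_bins(self, chrom: str) -> int:
        lo, hi = self._offsets[chrom]
        return hi - lo + 1

    def bin_index(self, chrom: str, pos: int) -> int:
        """Matrix row of the bin containing (chrom, pos)."""
        if chrom not in self._offsets:
            raise KeyError(f"no bins for chromosome {chrom}")
        lo, hi = self._offsets[chrom]
        idx = lo + pos // self.bin_size
        if idx > hi or pos < 0:
            raise KeyError(f"{chrom}:{pos} outside binned range")
        return idx

    def contact(self, chrom_a: str, pos_a: int, chrom_b: str, pos_b: int) -> float:
        return float(self.C[self.bin_index(chrom_a, pos_a), self.bin_index(chrom_b, pos_b)])

    def write(self, matrix_path: str | Path, bins_path: str | Path) -> None:
        self.bins.to_csv(bins_path, sep="\t", index=False)
        np.savetxt(matrix_path, self.C, fmt="%.6g")

    @classmethod
    def read(cls, matrix_path: str | Path, bins_path: str | Path, bin_size: int) -> "ContactModel":
        bins = pd.read_csv(bins_path, sep="\t")
        C = np.loadtxt(matrix_path)
        return cls(bin_size=bin_size, bins=bins, C=C)


def make_bins(genome: GenomeDefinition, bin_size: int) -> pd.DataFrame:
    """Bin every chromosome end to end; the last bin may be short."""
    rows = []
    for name, spec in genome.chromosomes.items():
        for start in range(0, spec.length, bin_size):
            rows.append((name, start, min(start + bin_size, spec.length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
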