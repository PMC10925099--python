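"""Site frequency spectrum container, folding, masking and dadi-style text I/O.

The SFS is the central observable: a vector of counts of variants by sample
allele-frequency class for a sample of ``n`` haploid chromosomes.  Folded
spectra tabulate minor-allele counts, so entries above ``n/2`` are empty and
masked.  Entries 0 and ``n`` (monomorphic classes) are always masked and never
enter a likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SFS", "SiteCounts", "read_sfs", "write_sfs", "fold"]


class SFSParseError(ValueError):
    """Raised when an SFS text file is malformed; names the offending line."""


def _default_mask(n: int, folded: bool) -> np.ndarray:
    mask = np.zeros(n + 1, dtype=bool)
    mask[0] = mask[n] = True
    if folded:
        mask[n // 2 + 1 :] = True
    return mask


@dataclass
class SFS:
    """A single-population site frequency spectrum.

    Parameters
    ----------
    counts
        Length ``n+1`` vector; entry ``i`` is the (possibly expected, hence
        real-valued) number of variants with derived/minor allele count ``i``.
    n
        Haploid sample size (864 chromosomes for the 432-diploid study data).
    folded
        Whether the spectrum tabulates minor-allele counts.
    mask
        Boolean per entry; ``True`` means excluded from all likelihood sums.
        Defaults to masking the monomorphic edges (and the upper half when
        folded).
    """

    counts: np.ndarray
    n: int
    folded: bool = False
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.shape[0] != self.n + 1:
            raise ValueError(
                f"counts must have length n+1={self.n + 1}, got {self.counts.shape}"
            )
        if self.mask is None:
            self.mask = _default_mask(self.n, self.folded)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask must have the same shape as counts")
        if np.any(self.counts[~self.mask] < 0):
            raise ValueError("unmasked SFS entries must be non-negative")

    @property
    def unmasked(self) -> np.ndarray:
        """Boolean selector for entries that enter likelihoods."""
        return ~self.mask

    def total(self) -> float:
        """Total count over unmasked entries."""
        return float(self.counts[self.unmasked].sum())

    def copy(self) -> "SFS":
        return SFS(self.counts.copy(), self.n, self.folded, self.mask.copy())

    def __mul__(self, scale: float) -> "SFS":
        return SFS(self.counts * scale, self.n, self.folded, self.mask.copy())

    __rmul__ = __mul__


@dataclass
class SiteCounts:
    """Counts of synonymous and nonsynonymous sites.

    ``L_NS`` defaults to ``ratio_NS_S * L_S`` (the study assumes a 2.31
    nonsynonymous:synonymous length ratio).
    """

    L_S: float
    ratio_NS_S: float = 2.31
    L_NS: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.L_NS is None:
            self.L_NS = self.ratio_NS_S * self.L_S
        if self.L_S <= 0 or self.L_NS <= 0 or self.ratio_NS_S <= 0:
            raise ValueError("site counts and ratio must be positive")


def fold(sfs: SFS) -> SFS:
    """Fold an unfolded spectrum onto minor-allele counts.

    ``folded[i] = counts[i] + counts[n-i]`` for ``i < n/2`` and the central
    entry (n even) is stored once.  Total unmasked count is conserved.
    """
    if sfs.folded:
        raise ValueError("spectrum is already folded")
    n = sfs.n
    half = n // 2
    counts = np.zeros(n + 1)
    for i in range(1, half + 1):
        j = n - i
        counts[i] = sfs.counts[i] + (sfs.counts[j] if j != i else 0.0)
    counts[0] = sfs.counts[0]
    return SFS(counts, n, folded=True)


def read_sfs(path: str | Path, strict_integer: bool = False) -> SFS:
    """Read a single-spectrum dadi-style SFS text file.

    The dialect is: a header line ``"<n+1> folded|unfolded"``, a line of
    ``n+1`` numbers, and a mask line of ``n+1`` 0/1 entries (1 = masked).
    Comment lines starting with ``#`` are ignored.
    """
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if len(lines) < 3:
        raise SFSParseError(f"{path}: expected header, data and mask lines")
    header = lines[0].split()
    if len(header) < 2 or header[1] not in ("folded", "unfolded"):
        raise SFSParseError(f"{path} line 1: bad header {lines[0]!r}")
    try:
        length = int(header[0])
    except ValueError:
        raise SFSParseError(f"{path} line 1: bad length in header {lines[0]!r}")
    folded = header[1] == "folded"
    try:
        counts = np.array([float(v) for v in lines[1].split()])
    except ValueError:
        raise SFSParseError(f"{path} line 2: non-numeric SFS entry")
    if counts.shape[0] != length:
        raise SFSParseError(
            f"{path} line 2: expected {length} entries, got {counts.shape[0]}"
        )
    mask_vals = lines[2].split()
    if len(mask_vals) != length:
        raise SFSParseError(
            f"{path} line 3: expected {length} mask entries, got {len(mask_vals)}"
        )
    if not all(v in ("0", "1") for v in mask_vals):
        raise SFSParseError(f"{path} line 3: mask entries must be 0 or 1")
    mask = np.array([v == "1" for v in mask_vals])
    if np.any(counts[~mask] < 0):
        raise SFSParseError(f"{path} line 2: negative unmasked count")
    if strict_integer and not np.allclose(counts[~mask] % 1.0, 0.0):
        raise SFSParseError(f"{path} line 2: non-integer observed count")
    return SFS(counts, n=length - 1, folded=folded, mask=mask)


def write_sfs(sfs: SFS, path: str | Path) -> None:
    """Write an SFS in the dadi-style dialect read by :func:`read_sfs`."""
    path = Path(path)
    kind = "folded" if sfs.folded else "unfolded"
    data = " ".join(
        f"{int(v)}" if float(v).is_integer() else repr(float(v)) for v in sfs.counts
    )
    maskline = " ".join("1" if m else "0" for m in sfs.mask)
    path.write_text(f"{sfs.n + 1} {kind}\n{data}\n{maskline}\n")
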