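"""Reading, validation and writing of bipartite interaction matrices.

The on-disk dialect is a delimited text matrix: the first row holds plant
labels (with an optional corner cell), each subsequent row holds one animal
label followed by its interaction values. Rows are animals (pollinators),
columns are plants; a ``transpose`` flag handles files stored the other way.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BipartiteNetwork",
    "NetworkFormatError",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "to_binary",
    "network_to_dict",
    "network_from_dict",
    "write_network_json",
]


class NetworkFormatError(ValueError):
    """Malformed input file (ragged rows, non-numeric cells, ...)."""


class NetworkValidationError(ValueError):
    """Structurally invalid network (zero-degree species, negatives, ...)."""


@dataclass(frozen=True)
class BipartiteNetwork:
    """A labeled animal x plant interaction matrix.

    Parameters
    ----------
    animal_labels, plant_labels
        Species names for the rows (pollinators) and columns (plants).
    M
        Nonnegative weight matrix of shape (A, P). Visit counts for
        weighted networks; any positive entry counts as an interaction.
    weighted
        Mode flag: if False, positive entries are treated as 1.
    allow_zero_degree
        Permit all-zero rows/columns. Only used for intermediate networks
        inside randomization ensembles; extinction runs reject such
        networks regardless.
    """

    animal_labels: tuple
    plant_labels: tuple
    M: np.ndarray
    weighted: bool = True
    allow_zero_degree: bool = field(default=False, compare=False, repr=False)

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 2:
            raise NetworkValidationError("M must be a 2-D matrix")
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "animal_labels", tuple(str(x) for x in self.animal_labels))
        object.__setattr__(self, "plant_labels", tuple(str(x) for x in self.plant_labels))
        A, P = M.shape
        if A < 1 or P < 1:
            raise NetworkValidationError("need at least one animal and one plant")
        if len(self.animal_labels) != A:
            raise NetworkValidationError(
                f"{len(self.animal_labels)} animal labels for {A} rows"
            )
        if len(self.plant_labels) != P:
            raise NetworkValidationError(
                f"{len(self.plant_labels)} plant labels for {P} columns"
            )
        for labels, guild in ((self.animal_labels, "animal"), (self.plant_labels, "plant")):
            if len(set(labels)) != len(labels):
                dupes = sorted({x for x in labels if labels.count(x) > 1})
                raise NetworkValidationError(f"duplicate {guild} labels: {dupes}")
        if np.any(M < 0):
            i, j = np.argwhere(M < 0)[0]
            raise NetworkValidationError(
                f"negative entry at ({self.animal_labels[i]}, {self.plant_labels[j]})"
            )
        if not np.any(M > 0):
            raise NetworkValidationError("network has no interactions")
        if not self.allow_zero_degree:
            zero_rows = np.flatnonzero(M.sum(axis=1) == 0)
            if zero_rows.size:
                names = [self.animal_labels[i] for i in zero_rows]
                raise NetworkValidationError(f"animal species with no interactions: {names}")
            zero_cols = np.flatnonzero(M.sum(axis=0) == 0)
            if zero_cols.size:
                names = [self.plant_labels[j] for j in zero_cols]
                raise NetworkValidationError(f"plant species with no interactions: {names}")
        if np.any(M != np.floor(M)):
            warnings.warn("non-integer interaction weights", stacklevel=3)
        M.setflags(write=False)

    # -- derived quantities -------------------------------------------------

    @property
    def n_animals(self) -> int:
        return self.M.shape[0]

    @property
    def n_plants(self) -> int:
        return self.M.shape[1]

    @property
    def n_edges(self) -> int:
        """Number of strictly positive entries (E)."""
        return int(np.count_nonzero(self.M))

    def binary_pattern(self) -> np.ndarray:
        """0/1 incidence pattern as a fresh integer array."""
        return (self.M > 0).astype(int)

    def effective_matrix(self) -> np.ndarray:
        """The matrix the current mode operates on (binarized if unweighted)."""
        return self.M.copy() if self.weighted else (self.M > 0).astype(float)

    def __eq__(self, other):
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return (
            self.animal_labels == other.animal_labels
            and self.plant_labels == other.plant_labels
            and self.weighted == other.weighted
            and self.M.shape == other.M.shape
            and bool(np.all(self.M == other.M))
        )


def to_binary(net: BipartiteNetwork) -> BipartiteNetwork:
    """Replace every positive weight with 1; labels and zero pattern kept."""
    return BipartiteNetwork(
        net.animal_labels,
        net.plant_labels,
        (net.M > 0).astype(float),
        weighted=False,
        allow_zero_degree=net.allow_zero_degree,
    )


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_network(
    path,
    delimiter: str | None = None,
    weighted: bool = True,
    transpose: bool = False,
) -> BipartiteNetwork:
    """Read a labeled delimited matrix file.

    The first row is the plant-label header, the first column the animal
    labels. ``transpose=True`` swaps that interpretation for files stored
    plants-by-animals.
    """
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise NetworkFormatError(f"{path}: empty file")
        delim = delimiter or _sniff_delimiter(first)
        fh.seek(0)
        rows = [row for row in csv.reader(fh, delimiter=delim)]
    header = rows[0]
    col_labels = [c.strip() for c in header[1:]]
    ncols = len(col_labels)
    if ncols == 0:
        raise NetworkFormatError(f"{path}: header has no column labels")
    row_labels = []
    values = []
    for rnum, row in enumerate(rows[1:], start=2):
        if not any(c.strip() for c in row):
            continue  # trailing blank line
        if len(row) != ncols + 1:
            raise NetworkFormatError(
                f"{path}: row {rnum} has {len(row)} cells, expected {ncols + 1}"
            )
        row_labels.append(row[0].strip())
        parsed = []
        for cnum, cell in enumerate(row[1:]):
            try:
                parsed.append(float(cell))
            except ValueError:
                raise NetworkFormatError(
                    f"{path}: non-numeric cell {cell!r} at row {rnum}, "
                    f"column {col_labels[cnum]!r}"
                ) from None
        values.append(parsed)
    if not values:
        raise NetworkFormatError(f"{path}: no data rows")
    M = np.array(values, dtype=float)
    if transpose:
        M = M.T
        row_labels, col_labels = col_labels, row_labels
    net = BipartiteNetwork(row_labels, col_labels, M, weighted=True)
    return net if weighted else to_binary(net)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_network(net: BipartiteNetwork, path, delimiter: str = ",") -> None:
    """Write the same dialect :func:`read_network` accepts."""
    M = net.M if net.weighted else net.binary_pattern()
    try:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter=delimiter)
            w.writerow([""] + list(net.plant_labels))
            for label, row in zip(net.animal_labels, M):
                w.writerow([label] + [_fmt(v) for v in row])
    except OSError as exc:
        raise OSError(f"cannot write network to {path}: {exc}") from exc


def network_to_dict(net: BipartiteNetwork) -> dict:
    return {
        "animal_labels": list(net.animal_labels),
        "plant_labels": list(net.plant_labels),
        "matrix": net.M.tolist(),
        "weighted": net.weighted,
    }


def network_from_dict(d: dict) -> BipartiteNetwork:
    return BipartiteNetwork(
        d["animal_labels"], d["plant_labels"], np.array(d["matrix"], dtype=float),
        weighted=bool(d["weighted"]),
    )


def write_network_json(net: BipartiteNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1)
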