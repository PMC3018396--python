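"""Feature encodings computed from the amino-acid sequence alone.

The encodings are the classic fixed-length summaries used for protein
classification: amino-acid composition (20), dipeptide composition (400),
gapped residue-pair compositions (400 per gap count), the 20x20
co-occurrence matrix of gapped pairs with its Haralick texture statistics
(12), fractions of residues in named physicochemical groups (48), and the
raw sequence length.

Conventions
-----------
* All pair vectors and the co-occurrence matrix use the canonical
  alphabetical residue order of :mod:`pinhub.io_formats`; a pair (a, b) is
  directional (first residue a, second residue b, row-major flattening).
* Nonstandard letters (B, J, O, U, X, Z) contribute to no numerator count,
  but the denominators stay the literal sequence-length expressions N,
  N - 1 and N - 1 - k, so vectors over sequences with nonstandard letters
  may sum to less than 1.
* Haralick statistics use base-2 logarithms with the 0*log(0) = 0
  convention; correlation is defined as 0 when a marginal is degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .io_formats import AA_INDEX, AMINO_ACIDS

__all__ = [
    "aac",
    "dipeptide_comp",
    "gapped_pair_comp",
    "cooccurrence_matrix",
    "haralick_features",
    "physicochemical_comp",
    "length_feature",
    "PropertyTable",
    "load_property_table",
    "pair_feature_names",
    "HARALICK_NAMES",
]

HARALICK_NAMES = (
    "energy",
    "correlation",
    "inertia",
    "entropy",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "information_measure_of_correlation",
)


def _encode(sequence: str) -> np.ndarray:
    """Map residues to canonical indices; nonstandard letters become -1."""
    if not sequence:
        raise ValueError("empty sequence")
    return np.array([AA_INDEX.get(c, -1) for c in sequence], dtype=np.int64)


def aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: fraction of each residue type, length 20."""
    idx = _encode(sequence)
    counts = np.bincount(idx[idx >= 0], minlength=20).astype(float)
    return counts / len(sequence)


def gapped_pair_comp(sequence: str, k: int) -> np.ndarray:
    """Composition of ordered residue pairs separated by exactly ``k`` gaps.

    Entry for the pair (a, b) counts positions i with sequence[i] == a and
    sequence[i + k + 1] == b, divided by N - 1 - k.  ``k = 0`` gives the
    dipeptide composition.
    """
    if k < 0:
        raise ValueError("gap count k must be >= 0")
    n = len(sequence)
    if n < k + 2:
        raise ValueError(f"sequence length {n} too short for gap {k} (need >= {k + 2})")
    idx = _encode(sequence)
    first = idx[: n - k - 1]
    second = idx[k + 1 :]
    valid = (first >= 0) & (second >= 0)
    pairs = first[valid] * 20 + second[valid]
    counts = np.bincount(pairs, minlength=400).astype(float)
    return counts / (n - 1 - k)


def dipeptide_comp(sequence: str) -> np.ndarray:
    """Dipeptide composition: fractions of adjacent ordered pairs, length 400."""
    if len(sequence) < 2:
        raise ValueError("dipeptide composition needs length >= 2")
    return gapped_pair_comp(sequence, 0)


def cooccurrence_matrix(sequence: str, k: int) -> np.ndarray:
    """20x20 matrix of gapped-pair frequencies; rows = first residue.

    Directional (not symmetrized): row-major flattening reproduces
    :func:`gapped_pair_comp` exactly.
    """
    return gapped_pair_comp(sequence, k).reshape(20, 20)


def _entropy2(p: np.ndarray) -> float:
    """Shannon entropy in bits with 0*log(0) = 0."""
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def haralick_features(matrix: np.ndarray) -> np.ndarray:
    """Twelve texture statistics of a co-occurrence matrix.

    Order: energy, correlation, inertia (contrast), entropy, inverse
    difference moment, sum average, sum variance, sum entropy, difference
    average, difference variance, difference entropy, information measure
    of correlation (first measure, IMC1).

    The matrix is renormalized to sum 1 first.  Sum/difference statistics
    are moments of the distributions of i + j and |i - j| over the
    normalized matrix (1-based indices); sum variance is taken about the
    sum average.
    """
    p = np.asarray(matrix, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    if np.any(p < 0):
        raise ValueError("co-occurrence matrix entries must be >= 0")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero co-occurrence matrix")
    p = p / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    energy = float((p ** 2).sum())

    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)
    if var_x > 0 and var_y > 0:
        correlation = float((np.outer(i, i) * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        correlation = 0.0

    diff = i[:, None] - i[None, :]
    inertia = float(((diff ** 2) * p).sum())
    entropy = _entropy2(p.ravel())
    idm = float((p / (1.0 + diff ** 2)).sum())

    # distribution of i + j (support 2..2*ng) and |i - j| (support 0..ng-1)
    p_sum = np.zeros(2 * ng - 1)
    p_diff = np.zeros(ng)
    for a in range(ng):
        for b in range(ng):
            p_sum[a + b] += p[a, b]
            p_diff[abs(a - b)] += p[a, b]
    ks = np.arange(2, 2 * ng + 1, dtype=float)
    kd = np.arange(ng, dtype=float)

    sum_average = float(ks @ p_sum)
    sum_variance = float(((ks - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy2(p_sum)
    difference_average = float(kd @ p_diff)
    difference_variance = float(((kd - difference_average) ** 2) @ p_diff)
    difference_entropy = _entropy2(p_diff)

    hx = _entropy2(px)
    hy = _entropy2(py)
    outer = np.outer(px, py)
    mask = (p > 0) & (outer > 0)
    hxy1 = float(-(p[mask] * np.log2(outer[mask])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0

    return np.array([
        energy, correlation, inertia, entropy, idm, sum_average, sum_variance,
        sum_entropy, difference_average, difference_variance, difference_entropy,
        imc1,
    ])


@dataclass
class PropertyTable:
    """Named residue groups used for physicochemical composition features."""

    names: list[str]
    groups: list[frozenset[str]]

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("empty property table")
        if len(self.names) != len(self.groups):
            raise ValueError("names/groups length mismatch")
        for name, group in zip(self.names, self.groups):
            bad = set(group) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"group {name!r}: non-standard members {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.names)


def load_property_table(path: str | Path | None = None) -> PropertyTable:
    """Load a property table TSV (``group_name TAB residue letters``).

    With no path, loads the packaged default: a 48-group synthetic stand-in
    assembled from standard residue classification schemes (the original
    48-property list is not publicly tabulated); only its aromatic group
    (H, F, W, Y) is definitional.
    """
    if path is None:
        source = resources.files("pinhub.data").joinpath("property_groups48_synthetic.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    names: list[str] = []
    groups: list[frozenset[str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, letters = line.partition("\t")
        names.append(name)
        groups.append(frozenset(letters.strip()))
    return PropertyTable(names, groups)


def physicochemical_comp(sequence: str, table: PropertyTable) -> np.ndarray:
    """Fraction of residues belonging to each property group."""
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    counts = np.array(
        [sum(1 for c in sequence if c in group) for group in table.groups],
        dtype=float,
    )
    return counts / n


def length_feature(sequence: str) -> np.ndarray:
    """Sequence length as a one-element feature vector."""
    return np.array([float(len(sequence))])


def pair_feature_names(prefix: str = "") -> list[str]:
    """Names of the 400 ordered-pair features in canonical row-major order."""
    return [f"{prefix}{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS]
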