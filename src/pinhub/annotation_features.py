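"""Feature encodings that require external annotations or profiles.

Covers binary domain-content and repeated-domain vectors, GO-term
membership vectors at a fixed ontology level, scalar summaries of
predicted disorder, and the two fixed-length PSSM encodings (PSSM-20 and
PSSM-400) derived from PSI-BLAST profiles.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, softmax

from .io_formats import (
    AMINO_ACIDS,
    AA_INDEX,
    DisorderMask,
    DomainAnnotation,
    GoAnnotation,
    PSSMProfile,
)

__all__ = [
    "domain_vector",
    "repeated_domain_vector",
    "go_level_vector",
    "disorder_features",
    "pssm20",
    "pssm400",
    "DISORDER_FEATURE_NAMES",
]

DISORDER_FEATURE_NAMES = (
    "disordered_fraction",
    "n_regions",
    "longest_region",
    "mean_region_length",
)


def domain_vector(
    annotation: DomainAnnotation | None,
    vocabulary: Sequence[str],
    *,
    lenient: bool = False,
) -> np.ndarray:
    """0/1 vector over ``vocabulary``: 1 iff the domain occurs in the protein.

    Domains absent from the vocabulary raise an error, or are dropped with
    a warning under ``lenient=True``.  ``annotation=None`` (unannotated
    protein) gives the all-zero vector.
    """
    if not vocabulary:
        raise ValueError("empty domain vocabulary")
    index = {d: i for i, d in enumerate(vocabulary)}
    out = np.zeros(len(vocabulary))
    if annotation is None:
        return out
    for dom in annotation.domains:
        pos = index.get(dom)
        if pos is None:
            if lenient:
                warnings.warn(f"domain {dom!r} not in vocabulary; dropped")
                continue
            raise KeyError(f"domain {dom!r} not in vocabulary")
        out[pos] = 1.0
    return out


def repeated_domain_vector(
    annotation: DomainAnnotation | None,
    family_vocabulary: Sequence[str],
    *,
    family_of: Mapping[str, str] | None = None,
    lenient: bool = False,
) -> np.ndarray:
    """0/1 vector: family cell is 1 iff two adjacent domains share that family.

    A repeated domain is two adjacent entries of the ordered domain list
    belonging to the same family.  ``family_of`` maps domain id -> family id
    and defaults to the identity (each domain its own family).
    """
    if not family_vocabulary:
        raise ValueError("empty family vocabulary")
    index = {f: i for i, f in enumerate(family_vocabulary)}
    out = np.zeros(len(family_vocabulary))
    if annotation is None or len(annotation.domains) < 2:
        return out
    families = [
        family_of.get(d, d) if family_of is not None else d
        for d in annotation.domains
    ]
    for a, b in zip(families, families[1:]):
        if a != b:
            continue
        pos = index.get(a)
        if pos is None:
            if lenient:
                warnings.warn(f"family {a!r} not in vocabulary; dropped")
                continue
            raise KeyError(f"family {a!r} not in vocabulary")
        out[pos] = 1.0
    return out


def go_level_vector(
    annotation: GoAnnotation | None,
    level: int,
    vocabulary: Sequence[str],
) -> np.ndarray:
    """0/1 membership vector over the GO terms of one ontology level.

    Terms missing from the vocabulary are dropped with a warning (GO
    releases drift); unannotated proteins get the all-zero vector.
    """
    if not vocabulary:
        raise ValueError("empty GO vocabulary")
    index = {t: i for i, t in enumerate(vocabulary)}
    out = np.zeros(len(vocabulary))
    if annotation is None:
        return out
    for term in annotation.terms_by_level.get(level, []):
        pos = index.get(term)
        if pos is None:
            warnings.warn(f"GO term {term!r} not in level-{level} vocabulary; dropped")
            continue
        out[pos] = 1.0
    return out


def disorder_features(mask: DisorderMask | None, sequence_length: int) -> np.ndarray:
    """Four scalar summaries of predicted disorder.

    (fraction of residues disordered, number of regions, longest region
    length, mean region length); all zero when there is no region.
    """
    if sequence_length <= 0:
        raise ValueError("sequence length must be positive")
    if mask is None or not mask.intervals:
        return np.zeros(4)
    intervals = mask.normalized().intervals
    for start, end in intervals:
        if start < 0 or end > sequence_length:
            raise ValueError(
                f"disorder interval [{start}, {end}) outside [0, {sequence_length})"
            )
    lengths = np.array([end - start for start, end in intervals], dtype=float)
    return np.array([
        lengths.sum() / sequence_length,
        float(len(lengths)),
        lengths.max(),
        lengths.mean(),
    ])


def pssm20(profile: PSSMProfile) -> np.ndarray:
    """Average residue-type usage among a protein's homologues, length 20.

    Column-wise mean of the profile's L x 20 percentage block, rescaled to
    fractions.  If the file carried no percentage block the observed-usage
    proxy is a softmax over the averaged log-odds scores (flagged with a
    warning).
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    if profile.percentages is not None:
        return profile.percentages.mean(axis=0) / 100.0
    warnings.warn("PSSM percentage block missing; using softmax of mean scores")
    return softmax(profile.scores.mean(axis=0))


def pssm400(profile: PSSMProfile) -> np.ndarray:
    """Residue-type-conditioned profile summary, length 400.

    For each residue type a (canonical order), block(a) is the mean of the
    20-dim score rows at sequence positions holding a, or zeros when a is
    absent; blocks are concatenated and squashed elementwise through the
    logistic 1/(1+exp(-x)), so absent types map to a uniform 0.5 block.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    blocks = np.zeros((20, 20))
    idx = np.array([AA_INDEX.get(c, -1) for c in profile.sequence])
    for a in range(20):
        rows = profile.scores[idx == a]
        if len(rows):
            blocks[a] = rows.mean(axis=0)
    return expit(blocks.ravel())
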