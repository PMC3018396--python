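"""Synthetic protein-interaction-network dataset generator.

Produces a labeled dataset with the statistical structure the hub-role
classifier assumes, so that every pipeline stage is testable without any
download: scale-free degrees, degree-threshold hub labels (non-hub < 3
interactions, hub > 8), a co-expression split of hubs into party and date
hubs, and class-conditional sequences, domain/GO/disorder annotations and
PSSM profiles.

Every class-dependent generator parameter is written ``base + effect_size
* delta_class``, so ``effect_size=0`` collapses all four classes onto one
distribution (features become pure noise) while the default
``effect_size=1`` gives the "strong effects" regime.  Effect directions
follow the biology the classifier banks on: hubs carry more domains and
more repeated domains than non-hubs, date hubs are the most disordered,
and each class tilts its residue composition, domain usage and cellular
compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import zipf

from .io_formats import (
    AMINO_ACIDS,
    Annotations,
    DisorderMask,
    DomainAnnotation,
    GoAnnotation,
    ProteinRecord,
    PSSMProfile,
    write_fasta,
    write_labels,
    write_pssm,
    write_vocabulary,
)

__all__ = [
    "SyntheticConfig",
    "generate_degrees",
    "assign_roles",
    "generate_protein",
    "generate_records",
    "generate_dataset",
    "GO_LEVELS",
]

#: Synthetic GO vocabularies: file "level" key -> (name, vocabulary size).
#: Three ontology aspects at two levels of detail; sizes follow the yeast
#: annotation (19/8/15 categories at the coarser level, 65/33/60 below it).
GO_LEVELS = {
    1: ("bp_l1", 19),
    2: ("bp_l2", 65),
    3: ("cc_l1", 8),
    4: ("cc_l2", 33),
    5: ("mf_l1", 15),
    6: ("mf_l2", 60),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``class_mix`` defaults to the yeast four-class frequencies
    (NH 81.4%, IC 9.8%, PH 3.3%, DH 5.5%); degree thresholds implement the
    "more than eight interactions is a hub, fewer than three a non-hub"
    convention; the party/date split uses average co-expression (avgPCC)
    against ``pcc_threshold``.
    """

    n_proteins: int = 2000
    seed: int = 0
    exponent: float = 2.5            # power-law exponent of the degree law
    hub_degree: int = 9              # degree >= 9  -> hub
    nonhub_degree: int = 3           # degree < 3   -> non-hub
    pcc_threshold: float = 0.5       # avgPCC >= threshold -> party hub
    class_mix: tuple[float, float, float, float] = (0.814, 0.098, 0.033, 0.055)
    effect_size: float = 1.0
    length_median: float = 450.0     # log-normal sequence length
    length_sigma: float = 0.45
    n_domain_vocab: int = 40
    composition_concentration: float = 100.0  # per-protein Dirichlet concentration

    def __post_init__(self) -> None:
        if self.nonhub_degree >= self.hub_degree:
            raise ValueError("non-hub degree threshold must be below hub threshold")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class mix must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path | None = None, **overrides) -> "SyntheticConfig":
        """Load conditions from a YAML file's ``synthetic`` section.

        With no path, loads the packaged strong-effects fixture.  Keyword
        overrides (e.g. ``seed``) win over file values.
        """
        import yaml
        from importlib import resources

        if path is None:
            text = resources.files("pinhub.data").joinpath(
                "strong_effects_config.yaml").read_text()
        else:
            text = Path(path).read_text()
        payload = (yaml.safe_load(text) or {}).get("synthetic", {})
        if "class_mix" in payload:
            payload["class_mix"] = tuple(payload["class_mix"])
        payload.update(overrides)
        return cls(**payload)


@dataclass
class _ClassParams:
    """Per-class generator parameters, derived deterministically from config."""

    compositions: np.ndarray      # (4, 20) residue distributions
    domain_prefs: np.ndarray      # (4, n_domain_vocab) domain usage
    domain_means: np.ndarray      # (4,) Poisson means for domain count
    repeat_probs: np.ndarray      # (4,) probability of a repeated domain
    go_prefs: dict[int, np.ndarray]  # level key -> (4, vocab size)
    disorder_fracs: np.ndarray    # (4,) target disordered fraction
    domain_vocab: list[str]
    go_vocabs: dict[int, list[str]]


def _mix(base: np.ndarray, direction: np.ndarray, effect: float,
         scale: float = 1.0) -> np.ndarray:
    """Convex tilt of a base distribution toward a class direction.

    weight = scale * effect / (1 + effect): effect 0 returns base exactly;
    ``scale`` sets the per-feature-family strength of the class signal
    (sequence composition is a weak discriminator in real interactomes,
    domain usage a strong one).
    """
    w = scale * effect / (1.0 + effect)
    out = (1 - w) * base + w * direction
    return out / out.sum()


def derive_class_params(config: SyntheticConfig) -> _ClassParams:
    """Class-conditional distributions; a pure function of the config."""
    rng = np.random.default_rng([config.seed % (2**31), 7721])
    effect = config.effect_size
    uniform_aa = np.full(20, 1 / 20)
    compositions = np.stack([
        _mix(uniform_aa, rng.dirichlet(np.ones(20)), effect, scale=0.3)
        for _ in range(4)
    ])
    # domain usage is the dominant class signal (hub roles track distinct,
    # concentrated domain repertoires); hubs are markedly multi-domain
    nd = config.n_domain_vocab
    uniform_dom = np.full(nd, 1 / nd)
    domain_prefs = np.stack([
        _mix(uniform_dom, rng.dirichlet(np.full(nd, 0.3)), effect, scale=0.8)
        for _ in range(4)
    ])
    domain_means = np.clip(1.8 + effect * np.array([-0.8, 0.2, 2.7, 2.7]), 0.2, None)
    repeat_probs = np.clip(0.08 + effect * np.array([-0.04, 0.02, 0.42, 0.42]), 0.0, 1.0)
    go_prefs: dict[int, np.ndarray] = {}
    go_vocabs: dict[int, list[str]] = {}
    for key, (name, size) in GO_LEVELS.items():
        uniform = np.full(size, 1 / size)
        go_prefs[key] = np.stack([
            _mix(uniform, rng.dirichlet(np.full(size, 0.4)), effect, scale=0.7)
            for _ in range(4)
        ])
        go_vocabs[key] = [f"{name.upper()}:{i:03d}" for i in range(size)]
    disorder_fracs = np.clip(
        0.12 + effect * np.array([-0.06, 0.0, 0.06, 0.30]), 0.0, 0.8
    )
    domain_vocab = [f"DOM{i:04d}" for i in range(nd)]
    return _ClassParams(
        compositions=compositions,
        domain_prefs=domain_prefs,
        domain_means=domain_means,
        repeat_probs=repeat_probs,
        go_prefs=go_prefs,
        disorder_fracs=disorder_fracs,
        domain_vocab=domain_vocab,
        go_vocabs=go_vocabs,
    )


# ---------------------------------------------------------------------------
# Network-side quantities: degrees, co-expression, roles
# ---------------------------------------------------------------------------

def generate_degrees(config: SyntheticConfig, n: int | None = None) -> np.ndarray:
    """Draw per-protein degrees from a discrete power law (Zipf, minimum 1)."""
    n = config.n_proteins if n is None else n
    if n < 10:
        raise ValueError("need at least 10 proteins")
    if config.exponent <= 1:
        raise ValueError("power-law exponent must exceed 1")
    rng = np.random.default_rng([config.seed % (2**31), 101])
    return zipf.rvs(config.exponent, size=n, random_state=rng)


def assign_roles(
    degrees: np.ndarray, avg_pcc: np.ndarray, config: SyntheticConfig
) -> np.ndarray:
    """Label proteins 1-4 from degree thresholds and hub co-expression.

    degree < nonhub_degree -> NH (1); degree < hub_degree -> IC (2);
    otherwise PH (3) if avgPCC >= pcc_threshold else DH (4).  A pure
    function of its inputs.
    """
    degrees = np.asarray(degrees)
    avg_pcc = np.asarray(avg_pcc)
    if degrees.shape != avg_pcc.shape:
        raise ValueError("degrees and avgPCC must align")
    labels = np.full(degrees.shape, 2, dtype=int)
    labels[degrees < config.nonhub_degree] = 1
    hubs = degrees >= config.hub_degree
    labels[hubs & (avg_pcc >= config.pcc_threshold)] = 3
    labels[hubs & (avg_pcc < config.pcc_threshold)] = 4
    return labels


def _truncated_zipf(rng: np.random.Generator, exponent: float,
                    low: int, high: int, size: int) -> np.ndarray:
    """Zipf degrees restricted to [low, high] via inverse-CDF sampling."""
    support = np.arange(low, high + 1)
    pmf = support.astype(float) ** (-exponent)
    pmf /= pmf.sum()
    return rng.choice(support, size=size, p=pmf)


def _sample_network(config: SyntheticConfig, rng: np.random.Generator,
                    n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (labels, degrees, avgPCC) hitting the target class mix.

    Labels are multinomial with the configured mix; degrees are then drawn
    from the power law truncated to the label's degree band, and hub avgPCC
    from the correct side of the co-expression threshold (party hubs high,
    date hubs low), so role assignment reproduces the labels exactly.
    """
    labels = rng.choice([1, 2, 3, 4], size=n, p=list(config.class_mix))
    degrees = np.empty(n, dtype=int)
    avg_pcc = np.empty(n)
    t = config.pcc_threshold
    for label, (low, high) in {
        1: (1, config.nonhub_degree - 1),
        2: (config.nonhub_degree, config.hub_degree - 1),
        3: (config.hub_degree, 10 * config.hub_degree),
        4: (config.hub_degree, 10 * config.hub_degree),
    }.items():
        mask = labels == label
        k = int(mask.sum())
        degrees[mask] = _truncated_zipf(rng, config.exponent, low, high, k)
        if label == 3:      # party hubs: co-expressed with their partners
            avg_pcc[mask] = t + (1 - t) * rng.beta(5, 2, size=k)
        elif label == 4:    # date hubs: low average co-expression
            avg_pcc[mask] = t * rng.beta(2, 5, size=k)
        else:
            avg_pcc[mask] = rng.uniform(0, 1, size=k)
    return labels, degrees, avg_pcc


# ---------------------------------------------------------------------------
# Per-protein record generation
# ---------------------------------------------------------------------------

def _make_pssm(sequence: str, protein_comp: np.ndarray,
               rng: np.random.Generator) -> PSSMProfile:
    """Emulate a PSI-BLAST profile: each position's homologue column is a
    noisy blend of the residue itself and the protein's own composition
    (homologues resemble the protein, so class information enters only
    through the protein-level composition, noise included)."""
    L = len(sequence)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    alpha = np.empty((L, 20))
    for pos, residue in enumerate(sequence):
        column = 0.5 * protein_comp.copy()
        idx = aa_index.get(residue)
        if idx is not None:
            column[idx] += 0.5
        else:
            column += 0.5 / 20
        alpha[pos] = 30.0 * column + 0.05
    draws = rng.gamma(alpha)
    fractions = draws / draws.sum(axis=1, keepdims=True)
    percentages = fractions * 100.0
    scores = np.round(2.0 * np.log2(np.maximum(fractions, 1e-3) / 0.05))
    return PSSMProfile(sequence=sequence, scores=scores, percentages=percentages)


def _make_disorder(length: int, target_fraction: float,
                   rng: np.random.Generator) -> DisorderMask:
    if target_fraction <= 0:
        return DisorderMask([])
    n_regions = 1 + rng.poisson(2.0 * target_fraction)
    total = max(int(target_fraction * length), 5)
    cuts = rng.dirichlet(np.ones(n_regions))
    intervals = []
    for share in cuts:
        span = max(int(share * total), 3)
        start = int(rng.integers(0, max(length - span, 1)))
        intervals.append((start, min(start + span, length)))
    return DisorderMask(intervals).normalized()


def generate_protein(
    config: SyntheticConfig,
    label: int,
    rng: np.random.Generator,
    params: _ClassParams | None = None,
) -> ProteinRecord:
    """Generate one fully-annotated protein record for a given class."""
    if label not in (1, 2, 3, 4):
        raise ValueError(f"invalid class label {label}")
    if params is None:
        params = derive_class_params(config)
    c = label - 1

    length = int(np.clip(
        rng.lognormal(math.log(config.length_median), config.length_sigma), 60, 3000
    ))
    composition = rng.dirichlet(config.composition_concentration * params.compositions[c])
    residues = rng.choice(list(AMINO_ACIDS), size=length, p=composition)
    sequence = "".join(residues)

    n_domains = rng.poisson(params.domain_means[c])
    domains = [
        params.domain_vocab[i]
        for i in rng.choice(len(params.domain_vocab), size=n_domains,
                            p=params.domain_prefs[c])
    ]
    if domains and rng.uniform() < params.repeat_probs[c]:
        pos = int(rng.integers(0, len(domains)))
        domains.insert(pos, domains[pos])  # adjacent same-family pair

    terms_by_level: dict[int, list[str]] = {}
    for key, prefs in params.go_prefs.items():
        vocab = params.go_vocabs[key]
        n_terms = 1 + rng.poisson(0.8)
        picks = rng.choice(len(vocab), size=min(n_terms, len(vocab)),
                           replace=False, p=prefs[c])
        terms_by_level[key] = [vocab[i] for i in sorted(picks)]

    # protein-level spread around the class mean fraction (Beta, nu=6),
    # so disorder is a noisy class signal rather than a deterministic one
    f_class = float(np.clip(params.disorder_fracs[c], 0.01, 0.95))
    nu = 10.0
    f_protein = rng.beta(f_class * nu, (1 - f_class) * nu)
    disorder = _make_disorder(length, f_protein, rng)
    pssm = _make_pssm(sequence, composition, rng)

    pid = f"SYN{rng.integers(0, 2**31):08x}"  # overwritten by generate_records
    return ProteinRecord(
        id=pid,
        sequence=sequence,
        annotations=Annotations(
            domains=DomainAnnotation(domains),
            go=GoAnnotation(terms_by_level),
            disorder=disorder,
            pssm=pssm,
        ),
    )


def generate_records(
    config: SyntheticConfig,
) -> tuple[list[ProteinRecord], dict[str, int], np.ndarray, np.ndarray]:
    """Generate the full in-memory dataset.

    Returns (records, labels map, degrees, avgPCC); records are named
    ``P000000`` .. in generation order and labels reproduce
    :func:`assign_roles` on (degrees, avgPCC) exactly.
    """
    rng = np.random.default_rng([config.seed % (2**31), 202])
    params = derive_class_params(config)
    labels_arr, degrees, avg_pcc = _sample_network(config, rng, config.n_proteins)
    records: list[ProteinRecord] = []
    labels: dict[str, int] = {}
    for i, label in enumerate(labels_arr):
        rec = generate_protein(config, int(label), rng, params)
        rec.id = f"P{i:06d}"
        records.append(rec)
        labels[rec.id] = int(label)
    return records, labels, degrees, avg_pcc


def generate_dataset(config: SyntheticConfig, out_dir: str | Path) -> Path:
    """Write a complete dataset consumable by the pipeline.

    Layout: ``proteins.fasta``, ``labels.tsv``, ``domains.tsv``, ``go.tsv``,
    ``disorder.tsv``, ``degrees.tsv``, vocabulary files and one ASCII PSSM
    per protein under ``pssm/``.  Deterministic per seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pssm_dir = out_dir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    params = derive_class_params(config)
    records, labels, degrees, avg_pcc = generate_records(config)

    write_fasta(out_dir / "proteins.fasta", records)
    write_labels(out_dir / "labels.tsv", labels)
    write_vocabulary(out_dir / "domain_vocab.txt", params.domain_vocab)
    for key, (name, _) in GO_LEVELS.items():
        write_vocabulary(out_dir / f"go_vocab_{name}.txt", params.go_vocabs[key])

    with open(out_dir / "domains.tsv", "w") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{';'.join(rec.annotations.domains.domains)}\n")
    with open(out_dir / "go.tsv", "w") as fh:
        for rec in records:
            for level, terms in rec.annotations.go.terms_by_level.items():
                for term in terms:
                    fh.write(f"{rec.id}\t{level}\t{term}\n")
    with open(out_dir / "disorder.tsv", "w") as fh:
        for rec in records:
            for start, end in rec.annotations.disorder.intervals:
                fh.write(f"{rec.id}\t{start}\t{end}\n")
    with open(out_dir / "degrees.tsv", "w") as fh:
        for rec, deg, pcc in zip(records, degrees, avg_pcc):
            fh.write(f"{rec.id}\t{deg}\t{pcc:.4f}\n")
    for rec in records:
        write_pssm(pssm_dir / f"{rec.id}.pssm", rec.annotations.pssm)
    return out_dir
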