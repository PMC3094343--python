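"""Synthetic admixed populations, dominant markers, and confounded phenotypes.

Markers are haploid dominant scores (a band is present or absent; no
heterozygote state exists anywhere in the pipeline).  Subpopulation allele
frequencies follow the Balding-Nichols model; accession ancestry proportions
are Dirichlet draws; phenotypes are built from a population term, optional
causal marker effects, a polygenic term with covariance ``sigma_g2 * K`` and
correlated residuals, with every component stored for downstream oracles.

This module also houses the marker preprocessing rules (per-allele SSR
binarization, most-frequent-allele reduction, allele-frequency filtering) and
the delimited-text I/O for marker and phenotype tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "MarkerMatrix",
    "PhenotypeTable",
    "SimTruth",
    "simulate_population",
    "simulate_markers",
    "simulate_phenotypes",
    "simulate_dataset",
    "binarize_ssr",
    "most_frequent_allele_subset",
    "filter_markers",
    "read_marker_matrix",
    "read_phenotype_table",
    "write_matrix",
    "write_truth",
]


class FormatError(ValueError):
    """Raised for malformed delimited-text inputs."""


def _ar1_corr(n_traits: int, rho: float = 0.5) -> np.ndarray:
    idx = np.arange(n_traits)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class SimConfig:
    """Parameters of one synthetic collection.

    Defaults emulate a typical genebank association panel: a core collection
    of ~168 accessions in 4 heavily admixed subpopulations scored for a few
    hundred dominant binary markers and ~11 correlated metabolite traits whose
    means differ by subpopulation.
    """

    n_accessions: int = 168
    n_subpops: int = 4
    fst: float = 0.25
    admix_alpha: float = 0.5
    n_markers: int = 400
    causal_effects: Mapping[int, float] = field(default_factory=dict)
    pop_effects: Sequence[float] | None = None
    sigma_g2: float = 0.0
    sigma_e2: float = 1.0
    n_traits: int = 1
    trait_corr: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 1 or self.n_markers < 1 or self.n_traits < 1:
            raise ValueError("counts must be positive")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must lie in (0, 1), got {self.fst}")
        if self.admix_alpha <= 0:
            raise ValueError("admix_alpha must be > 0")
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        if self.pop_effects is not None:
            pe = np.asarray(self.pop_effects, dtype=float)
            if pe.shape != (self.n_subpops,):
                raise ValueError("pop_effects must have one entry per subpopulation")
        for j in self.causal_effects:
            if not 0 <= j < self.n_markers:
                raise ValueError(f"causal marker index {j} out of range")

    def resolved_trait_corr(self) -> np.ndarray:
        if self.trait_corr is None:
            return _ar1_corr(self.n_traits)
        C = np.asarray(self.trait_corr, dtype=float)
        if C.shape != (self.n_traits, self.n_traits):
            raise ValueError("trait_corr must be n_traits x n_traits")
        return C


@dataclass
class MarkerMatrix:
    """Accessions x markers binary dominant scores with marker metadata."""

    scores: np.ndarray
    accession_ids: list[str]
    marker_names: list[str]
    marker_types: list[str] = field(default_factory=list)
    ssr_locus_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D")
        if not np.isin(self.scores, (0, 1)).all():
            raise ValueError("marker scores must be strictly binary")
        self.scores = self.scores.astype(np.int8)
        n, m = self.scores.shape
        if len(self.accession_ids) != n or len(self.marker_names) != m:
            raise ValueError("id/name lengths do not match score matrix")
        if not self.marker_types:
            self.marker_types = ["AFLP"] * m
        if len(self.marker_types) != m:
            raise ValueError("marker_types length mismatch")

    @property
    def n_accessions(self) -> int:
        return self.scores.shape[0]

    @property
    def n_markers(self) -> int:
        return self.scores.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-marker fraction of 1s, recomputed from the realized scores."""
        return self.scores.mean(axis=0)

    def subset(self, keep: np.ndarray) -> "MarkerMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        names = [self.marker_names[j] for j in keep]
        return MarkerMatrix(
            scores=self.scores[:, keep],
            accession_ids=list(self.accession_ids),
            marker_names=names,
            marker_types=[self.marker_types[j] for j in keep],
            ssr_locus_of={k: v for k, v in self.ssr_locus_of.items() if k in set(names)},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=pd.Index(self.accession_ids, name="accession"),
            columns=self.marker_names,
        )


@dataclass
class PhenotypeTable:
    """Accessions x traits real-valued phenotypes."""

    values: np.ndarray
    accession_ids: list[str]
    trait_names: list[str]
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype values must be finite")
        n, t = self.values.shape
        if len(self.accession_ids) != n or len(self.trait_names) != t:
            raise ValueError("id/name lengths do not match value matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.accession_ids, name="accession"),
            columns=self.trait_names,
        )


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset; components sum exactly to y."""

    true_Q: "object"  # popstruct.AdmixtureQ
    subpop_allele_freqs: np.ndarray
    causal_markers: dict[int, float]
    pop_component: np.ndarray
    marker_component: np.ndarray
    polygenic_component: np.ndarray
    noise_component: np.ndarray
    eigen_clip: float = 0.0

    def total(self) -> np.ndarray:
        return (
            self.pop_component
            + self.marker_component
            + self.polygenic_component
            + self.noise_component
        )


# ---------------------------------------------------------------------------
# simulation

def simulate_population(cfg: SimConfig):
    """Draw admixture proportions and subpopulation allele frequencies.

    Ancestral frequencies are uniform on [0.1, 0.9] (avoids near-fixed loci
    dominating the divergence draw); subpopulation frequencies follow
    Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F); each accession's membership
    row is Dirichlet(admix_alpha).
    """
    from .popstruct import AdmixtureQ  # deferred: popstruct imports this module

    rng = np.random.default_rng(cfg.seed)
    p_anc = rng.uniform(0.1, 0.9, size=cfg.n_markers)
    F = cfg.fst
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    P = rng.beta(a, b, size=(cfg.n_subpops, cfg.n_markers))
    if cfg.n_subpops == 1:
        Q = np.ones((cfg.n_accessions, 1))
    else:
        Q = rng.dirichlet(np.full(cfg.n_subpops, cfg.admix_alpha), size=cfg.n_accessions)
    ids = [f"acc{i:04d}" for i in range(cfg.n_accessions)]
    return AdmixtureQ(memberships=Q, accession_ids=ids), P


def simulate_markers(Q, subpop_allele_freqs: np.ndarray, n_markers: int | None = None,
                     seed: int = 0) -> MarkerMatrix:
    """Draw dominant scores: score_ij ~ Bernoulli(sum_k Q_ik p_kj)."""
    P = np.asarray(subpop_allele_freqs, dtype=float)
    Qm = Q.memberships
    if Qm.shape[1] != P.shape[0]:
        raise ValueError(
            f"Q has {Qm.shape[1]} subpopulations but frequency matrix has {P.shape[0]} rows"
        )
    if n_markers is not None:
        if n_markers > P.shape[1]:
            raise ValueError("n_markers exceeds available frequency columns")
        P = P[:, :n_markers]
    probs = Qm @ P
    rng = np.random.default_rng(seed)
    scores = (rng.random(probs.shape) < probs).astype(np.int8)
    names = [f"m{j:04d}" for j in range(P.shape[1])]
    return MarkerMatrix(scores=scores, accession_ids=list(Q.accession_ids),
                        marker_names=names)


def _psd_sqrt(K: np.ndarray) -> tuple[np.ndarray, float]:
    """Symmetric PSD square root with negative eigenvalues clipped at 0."""
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    clip = float(np.abs(w[w < 0]).sum())
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w), clip


def simulate_phenotypes(markers: MarkerMatrix, Q, K, cfg: SimConfig
                        ) -> tuple[PhenotypeTable, SimTruth]:
    """Simulate y = Q.pop_effects + sum_j beta_j marker_j + g + eps.

    g ~ MVN(0, sigma_g2 * K) independently per trait; eps rows share the
    configured trait correlation.  All four components are stored in the
    returned :class:`SimTruth` and sum to y exactly.
    """
    Kv = K.values if hasattr(K, "values") else np.asarray(K, dtype=float)
    n = markers.n_accessions
    T = cfg.n_traits
    if Kv.shape != (n, n):
        raise ValueError("kinship matrix shape mismatch")
    for j in cfg.causal_effects:
        if not 0 <= j < markers.n_markers:
            raise ValueError(f"causal marker index {j} out of range")

    rng = np.random.default_rng(cfg.seed + 1)
    Qm = Q.memberships
    if cfg.pop_effects is None:
        pop = np.zeros(n)
    else:
        pop = Qm @ np.asarray(cfg.pop_effects, dtype=float)
    marker = np.zeros(n)
    for j, beta in cfg.causal_effects.items():
        marker = marker + beta * markers.scores[:, j].astype(float)

    L, clip = _psd_sqrt(Kv)
    if clip > 1e-8:
        logger.info("kinship eigen-clip applied: total negative mass %.3g", clip)
    g = np.sqrt(cfg.sigma_g2) * (L @ rng.standard_normal((n, T)))
    C = cfg.resolved_trait_corr()
    Lc, _ = _psd_sqrt(C)
    eps = np.sqrt(cfg.sigma_e2) * (rng.standard_normal((n, T)) @ Lc.T)

    pop_c = np.repeat(pop[:, None], T, axis=1)
    marker_c = np.repeat(marker[:, None], T, axis=1)
    y = pop_c + marker_c + g + eps
    traits = [f"trait{t:02d}" for t in range(T)]
    pheno = PhenotypeTable(values=y, accession_ids=list(markers.accession_ids),
                           trait_names=traits)
    truth = SimTruth(
        true_Q=Q,
        subpop_allele_freqs=np.empty((0, 0)),
        causal_markers=dict(cfg.causal_effects),
        pop_component=pop_c,
        marker_component=marker_c,
        polygenic_component=g,
        noise_component=eps,
        eigen_clip=clip,
    )
    return pheno, truth


def simulate_dataset(cfg: SimConfig):
    """Full generative chain: population -> markers -> kinship -> phenotypes.

    Returns (markers, phenotypes, truth).  The kinship used for the polygenic
    term is the frequency-corrected estimate from the simulated markers
    themselves (the same marker set feeds K and Q, as in real panels).
    """
    from .kinship import kinship_freq_corrected

    Q, P = simulate_population(cfg)
    markers = simulate_markers(Q, P, seed=cfg.seed + 7)
    if cfg.sigma_g2 > 0:
        poly = (markers.allele_freq > 0) & (markers.allele_freq < 1)
        K = kinship_freq_corrected(markers.subset(poly)).values
    else:
        K = np.eye(cfg.n_accessions)
    pheno, truth = simulate_phenotypes(markers, Q, K, cfg)
    truth.subpop_allele_freqs = P
    return markers, pheno, truth


# ---------------------------------------------------------------------------
# marker preprocessing

def binarize_ssr(calls: Mapping[str, Sequence[Sequence[str]]],
                 accession_ids: Sequence[str]) -> MarkerMatrix:
    """Convert multi-allelic locus calls to binary per-allele columns.

    ``calls`` maps locus name -> per-accession collections of observed
    alleles.  One column is emitted per distinct observed allele (1 iff the
    accession carries it), grouped by locus; empty loci are skipped with a
    warning.
    """
    n = len(accession_ids)
    cols, names, types = [], [], []
    locus_of: dict[str, str] = {}
    for locus, per_acc in calls.items():
        if len(per_acc) != n:
            raise ValueError(f"locus {locus!r} has {len(per_acc)} call rows, expected {n}")
        alleles = sorted({a for row in per_acc for a in row})
        if not alleles:
            warnings.warn(f"locus {locus!r} has no observed alleles; skipped")
            continue
        for allele in alleles:
            name = f"{locus}_{allele}"
            cols.append([1 if allele in row else 0 for row in per_acc])
            names.append(name)
            types.append("SSR")
            locus_of[name] = locus
    scores = np.array(cols, dtype=np.int8).T if cols else np.zeros((n, 0), dtype=np.int8)
    return MarkerMatrix(scores=scores, accession_ids=list(accession_ids),
                        marker_names=names, marker_types=types, ssr_locus_of=locus_of)


def most_frequent_allele_subset(markers: MarkerMatrix) -> MarkerMatrix:
    """Keep only the most frequent allele column of each SSR locus.

    Avoids over-representing multi-allelic loci in structure/kinship input.
    Non-SSR columns pass through; ties break toward the first column.
    """
    if not markers.ssr_locus_of:
        return markers
    freq = markers.allele_freq
    best: dict[str, int] = {}
    for j, name in enumerate(markers.marker_names):
        locus = markers.ssr_locus_of.get(name)
        if locus is None:
            continue
        if locus not in best or freq[j] > freq[best[locus]]:
            best[locus] = j
    winners = set(best.values())
    keep = [j for j, name in enumerate(markers.marker_names)
            if name not in markers.ssr_locus_of or j in winners]
    return markers.subset(np.array(keep, dtype=int))


def filter_markers(markers: MarkerMatrix, min_freq: float = 0.10) -> MarkerMatrix:
    """Keep markers with min_freq < allele frequency < 1 - min_freq (strict).

    The symmetric upper cut drops near-ubiquitous bands, which carry as little
    information as near-absent ones.
    """
    freq = markers.allele_freq
    keep = (freq > min_freq) & (freq < 1.0 - min_freq)
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValueError("no markers pass frequency filter")
    logger.info("frequency filter: kept %d of %d markers", n_kept, markers.n_markers)
    return markers.subset(keep)


# ---------------------------------------------------------------------------
# delimited-text I/O

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicated accession id {dup!r} in {path}")
    return df


def read_marker_matrix(path: str | Path, meta_path: str | Path | None = None
                       ) -> MarkerMatrix:
    """Read a marker TSV/CSV (rows=accessions, binary cells, header names)."""
    df = _read_table(path)
    arr = np.empty(df.shape, dtype=np.int8)
    for jc, col in enumerate(df.columns):
        for ic, (acc, raw) in enumerate(df[col].items()):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or pd.isna(raw):
                raise FormatError(
                    f"missing marker value at (row {acc!r}, column {col!r}); "
                    "missing data is unsupported")
            if raw not in ("0", "1"):
                raise FormatError(
                    f"non-binary value {raw!r} at (row {acc!r}, column {col!r})")
            arr[ic, jc] = int(raw)
    types = ["AFLP"] * df.shape[1]
    locus_of: dict[str, str] = {}
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("name")
        types = [str(meta.loc[c, "type"]) if c in meta.index else "AFLP"
                 for c in df.columns]
        for c in df.columns:
            if c in meta.index and isinstance(meta.loc[c].get("locus"), str):
                locus_of[c] = meta.loc[c, "locus"]
    return MarkerMatrix(scores=arr, accession_ids=[str(i) for i in df.index],
                        marker_names=[str(c) for c in df.columns],
                        marker_types=types, ssr_locus_of=locus_of)


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    df = _read_table(path)
    try:
        vals = df.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric phenotype value in {path}: {exc}") from exc
    if np.isnan(vals).any():
        i, j = map(int, np.argwhere(np.isnan(vals))[0])
        raise FormatError(
            f"missing phenotype value at (row {df.index[i]!r}, column {df.columns[j]!r})")
    return PhenotypeTable(values=vals, accession_ids=[str(i) for i in df.index],
                          trait_names=[str(c) for c in df.columns])


def write_matrix(obj: MarkerMatrix | PhenotypeTable, path: str | Path) -> None:
    """Write a marker or phenotype table as TSV/CSV (extension decides).

    Marker matrices also get a ``<path>.meta.tsv`` sidecar with marker name,
    type, and SSR locus grouping.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    obj.to_frame().to_csv(path, sep=sep)
    if isinstance(obj, MarkerMatrix):
        meta = pd.DataFrame({
            "name": obj.marker_names,
            "type": obj.marker_types,
            "locus": [obj.ssr_locus_of.get(n, "") for n in obj.marker_names],
        })
        meta.to_csv(path.with_suffix(path.suffix + ".meta.tsv"), sep="\t", index=False)


def write_truth(truth: SimTruth, outdir: str | Path, cfg: SimConfig | None = None) -> None:
    """Serialize a SimTruth as a directory of TSVs plus a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = truth.true_Q.accession_ids
    for name, comp in (
        ("pop_component", truth.pop_component),
        ("marker_component", truth.marker_component),
        ("polygenic_component", truth.polygenic_component),
        ("noise_component", truth.noise_component),
    ):
        pd.DataFrame(comp, index=pd.Index(ids, name="accession")).to_csv(
            outdir / f"{name}.tsv", sep="\t")
    pd.DataFrame(truth.true_Q.memberships, index=pd.Index(ids, name="accession")).to_csv(
        outdir / "true_Q.tsv", sep="\t")
    if truth.subpop_allele_freqs.size:
        pd.DataFrame(truth.subpop_allele_freqs).to_csv(
            outdir / "subpop_allele_freqs.tsv", sep="\t")
    pd.DataFrame(sorted(truth.causal_markers.items()),
                 columns=["marker_index", "effect"]).to_csv(
        outdir / "causal_markers.tsv", sep="\t", index=False)
    if cfg is not None:
        with open(outdir / "config.yaml", "w") as fh:
            for key in ("n_accessions", "n_subpops", "fst", "admix_alpha", "n_markers",
                        "sigma_g2", "sigma_e2", "n_traits", "seed"):
                fh.write(f"{key}: {getattr(cfg, key)}\n")
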