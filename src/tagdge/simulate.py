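"""Ground-truthed simulator for tag-based DGE experiments.

The generator produces everything the pipeline consumes, with full per-read
provenance so every downstream stage can be checked against planted truth:

* a transcriptome of i.i.d. random-DNA transcripts with log-normal lengths,
  optionally guaranteed to carry at least ``min_usable_sites`` usable CATG
  sites (a site needs >= 17 nt downstream to yield a tag);
* per-condition gene abundances: log-normal across genes, with a planted
  fraction of DE genes whose abundance is scaled by 2^(+-log2FC) between
  consecutive conditions;
* tag libraries: each read picks a gene proportionally to abundance, then a
  site — the canonical (3'-most) one with probability d (digestion
  completeness), otherwise a uniformly chosen upstream usable site (genes
  with a single site can only emit canonical tags); each base is substituted
  independently with probability e; N-containing and adaptor-only
  contaminant reads are injected at configured fractions.

All randomness flows from one seed through numpy SeedSequence spawning, so
every output is byte-reproducible.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import RawTagLibrary
from .reference import TAG_LEN, Transcript, extract_virtual_tags

_BASES = np.array(list("ACGT"))

#: provenance codes for contaminant classes
READ_REAL, READ_N_TAG, READ_ADAPTOR = 0, 1, 2


class ImpossibleConstraintError(ValueError):
    """Config asks for something unsatisfiable (e.g. guaranteed CATG sites in
    transcripts shorter than a tag)."""


class AllGenesInvisibleError(ValueError):
    """No expressed gene has a usable CATG site."""


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic DGE experiment.

    Defaults describe a desk-scale analogue of a whole-organism insect
    developmental series: a few thousand genes with ~300 nt assembled
    transcripts, log-normal expression spanning several orders of magnitude,
    10% of genes planted as 4-fold DE between consecutive stages, ~60%
    complete NlaIII digestion, 0.1% per-base sequencing error and about
    1.5% contaminant reads.
    """

    n_genes: int = 2000
    length_meanlog: float = math.log(300.0)
    length_sdlog: float = 0.35
    min_length: int = 60
    guarantee_catg: bool = True
    min_usable_sites: int = 1
    expr_meanlog: float = 0.0
    expr_sdlog: float = 1.5
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    library_size: int = 500_000
    digestion_completeness: float = 0.6
    per_base_error_rate: float = 0.001
    frac_n_tags: float = 0.01
    frac_adaptor_only: float = 0.005
    adaptor_seq: str = "TCGTATGCCGTCTTCTGCTTG"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "de_fraction", "digestion_completeness", "per_base_error_rate",
            "frac_n_tags", "frac_adaptor_only",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_genes < 1 or self.library_size < 1:
            raise ValueError("n_genes and library_size must be >= 1")
        if self.guarantee_catg and self.min_length < TAG_LEN:
            raise ImpossibleConstraintError(
                f"guarantee_catg requires min_length >= {TAG_LEN}"
            )
        if self.guarantee_catg and self.min_usable_sites * 25 > self.min_length:
            raise ImpossibleConstraintError(
                "min_length too short for the requested number of planted sites"
            )

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-condition abundances, DE labels per
    consecutive condition pair, and per-library read provenance."""

    config: SimulationConfig
    gene_ids: list[str]
    abundance: pd.DataFrame  # genes x conditions, relative abundances
    de_labels: dict[tuple[str, str], pd.DataFrame]  # pair -> (is_de, true_log2fc)
    provenance: dict[str, pd.DataFrame] = field(default_factory=dict)
    invisible_genes: list[str] = field(default_factory=list)

    def true_de_genes(self, pair: tuple[str, str]) -> pd.Index:
        lab = self.de_labels[pair]
        return lab.index[lab.is_de]


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def simulate_transcriptome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[Transcript]:
    """Random-DNA transcriptome with log-normal lengths.

    With ``guarantee_catg``, ``min_usable_sites`` CATG sites are planted in
    the 3' region (the 3'-most at length-21, further ones spaced 25 nt
    upstream) so every gene can emit at least one tag; planting overwrites
    4 nt and cannot be disrupted afterwards.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lengths = np.maximum(
        cfg.min_length,
        np.rint(rng.lognormal(cfg.length_meanlog, cfg.length_sdlog, cfg.n_genes)),
    ).astype(int)
    width = len(str(cfg.n_genes - 1))
    out = []
    for i, L in enumerate(lengths):
        arr = _random_dna(rng, L)
        if cfg.guarantee_catg:
            for k in range(cfg.min_usable_sites):
                pos = L - TAG_LEN - 25 * k
                arr[pos : pos + 4] = list("CATG")
        out.append(Transcript(gene_id=f"gene{i:0{width}d}", sequence="".join(arr)))
    return out


def simulate_abundances(
    cfg: SimulationConfig,
    conditions: Sequence[str],
    rng: np.random.Generator | None = None,
    *,
    eligible: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], pd.DataFrame]]:
    """Log-normal base abundances plus chained planted DE.

    Condition k+1 inherits condition k's abundances, then an independently
    drawn set of round(de_fraction * n_eligible) genes is scaled by
    2^(+-de_log2fc) with random sign.  ``eligible`` restricts the DE-able
    genes (e.g. to genes with a usable tag site).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_genes - 1))
    genes = pd.Index([f"gene{i:0{width}d}" for i in range(cfg.n_genes)], name="gene_id")
    base = rng.lognormal(cfg.expr_meanlog, cfg.expr_sdlog, cfg.n_genes)
    abundance = pd.DataFrame(index=genes, columns=list(conditions), dtype=float)
    abundance[conditions[0]] = base
    eligible_idx = genes if eligible is None else pd.Index(eligible)
    n_de = round(cfg.de_fraction * len(eligible_idx))
    de_labels: dict[tuple[str, str], pd.DataFrame] = {}
    for c_prev, c_next in zip(conditions, conditions[1:]):
        chosen = rng.choice(len(eligible_idx), size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        lfc = pd.Series(0.0, index=genes)
        lfc.loc[eligible_idx[np.sort(chosen)]] = (
            signs[np.argsort(chosen)] * cfg.de_log2fc
        )
        abundance[c_next] = abundance[c_prev] * np.power(2.0, lfc)
        de_labels[(c_prev, c_next)] = pd.DataFrame(
            {"is_de": lfc != 0.0, "true_log2fc": lfc}
        )
    return abundance, de_labels


def _gene_sites(transcripts: Sequence[Transcript]):
    """Per gene: ascending usable site positions and their tag strings."""
    sites, tags = {}, {}
    for t in transcripts:
        vts = extract_virtual_tags(t)
        if vts:
            sites[t.gene_id] = [v.site_pos for v in vts]
            tags[t.gene_id] = [v.tag_seq for v in vts]
    return sites, tags


def simulate_tag_library(
    transcripts: Sequence[Transcript],
    abundance: Mapping[str, float] | pd.Series,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str,
) -> tuple[RawTagLibrary, pd.DataFrame]:
    """Draw one raw tag library of cfg.library_size reads.

    Returns the raw library plus per-read provenance (gene index -1 for
    contaminants, site position, canonical flag, error count, read class).
    """
    abundance = pd.Series(abundance, dtype=float)
    sites, tag_strs = _gene_sites(transcripts)
    gene_ids = [g for g in abundance.index if g in sites]
    if not gene_ids:
        raise AllGenesInvisibleError("no expressed gene has a usable CATG site")
    p = abundance.loc[gene_ids].to_numpy()
    p = p / p.sum()

    n = cfg.library_size
    n_ntag, n_adaptor, n_real = rng.multinomial(
        n, [cfg.frac_n_tags, cfg.frac_adaptor_only,
            1.0 - cfg.frac_n_tags - cfg.frac_adaptor_only]
    )

    gene_draw = rng.choice(len(gene_ids), size=n_real, p=p)
    gene_counts = np.bincount(gene_draw, minlength=len(gene_ids))
    reads: list[str] = []
    prov_gene: list[int] = []
    prov_site: list[int] = []
    prov_canon: list[bool] = []
    d = cfg.digestion_completeness
    for gi, cnt in enumerate(gene_counts):
        if cnt == 0:
            continue
        g = gene_ids[gi]
        gsites, gtags = sites[g], tag_strs[g]
        if len(gsites) == 1:
            per_site = {len(gsites) - 1: cnt}
        else:
            n_canon = rng.binomial(cnt, d)
            per_site = {len(gsites) - 1: n_canon}
            if cnt - n_canon:
                alt = rng.multinomial(
                    cnt - n_canon,
                    np.full(len(gsites) - 1, 1.0 / (len(gsites) - 1)),
                )
                for si, c in enumerate(alt):
                    if c:
                        per_site[si] = per_site.get(si, 0) + c
        for si, c in sorted(per_site.items()):
            reads.extend([gtags[si]] * c)
            prov_gene.extend([gi] * c)
            prov_site.extend([gsites[si]] * c)
            prov_canon.extend([si == len(gsites) - 1] * c)

    # per-base substitution errors on real reads
    n_err = rng.binomial(TAG_LEN, cfg.per_base_error_rate, size=n_real)
    for ridx in np.nonzero(n_err)[0]:
        arr = list(reads[ridx])
        pos = rng.choice(TAG_LEN, size=n_err[ridx], replace=False)
        for pidx in pos:
            alts = [b for b in "ACGT" if b != arr[pidx]]
            arr[pidx] = alts[rng.integers(0, 3)]
        reads[ridx] = "".join(arr)

    # contaminants: N-corrupted real-style tags and adaptor-only reads
    for _ in range(n_ntag):
        gi = rng.choice(len(gene_ids), p=p)
        g = gene_ids[gi]
        si = rng.integers(0, len(sites[g]))
        arr = list(tag_strs[g][si])
        # Ns only in the 17 variable nt: an N in the anchor would reclassify
        # the read as adaptor_or_empty and decouple the audit from truth
        for pidx in rng.choice(np.arange(4, TAG_LEN), size=rng.integers(1, 4), replace=False):
            arr[pidx] = "N"
        reads.append("".join(arr))
        prov_gene.append(-1)
        prov_site.append(-1)
        prov_canon.append(False)
    reads.extend([cfg.adaptor_seq] * n_adaptor)
    prov_gene.extend([-1] * n_adaptor)
    prov_site.extend([-1] * n_adaptor)
    prov_canon.extend([False] * n_adaptor)

    klass = np.concatenate([
        np.full(n_real, READ_REAL),
        np.full(n_ntag, READ_N_TAG),
        np.full(n_adaptor, READ_ADAPTOR),
    ]).astype(np.int8)
    prov = pd.DataFrame(
        {
            "gene_index": np.asarray(prov_gene, dtype=np.int64),
            "site_pos": np.asarray(prov_site, dtype=np.int64),
            "is_canonical": np.asarray(prov_canon, dtype=bool),
            "n_errors": np.concatenate([n_err, np.zeros(n_ntag + n_adaptor, dtype=int)]),
            "read_class": klass,
        }
    )
    prov.attrs["gene_ids"] = gene_ids
    return RawTagLibrary(sample_id=sample_id, reads=Counter(reads)), prov


@dataclass
class SimulatedExperiment:
    transcripts: list[Transcript]
    truth: SyntheticTruth
    libraries: dict[str, RawTagLibrary]


def simulate_experiment(
    cfg: SimulationConfig, conditions: Sequence[str] = ("cond1", "cond2")
) -> SimulatedExperiment:
    """Full experiment: transcriptome, chained per-condition abundances with
    planted DE, and one raw tag library per condition."""
    ss = np.random.SeedSequence(cfg.seed)
    kids = ss.spawn(2 + len(conditions))
    transcripts = simulate_transcriptome(cfg, np.random.default_rng(kids[0]))
    sites, _ = _gene_sites(transcripts)
    abundance, de_labels = simulate_abundances(
        cfg, conditions, np.random.default_rng(kids[1]), eligible=sorted(sites)
    )
    truth = SyntheticTruth(
        config=cfg,
        gene_ids=[t.gene_id for t in transcripts],
        abundance=abundance,
        de_labels=de_labels,
        invisible_genes=[t.gene_id for t in transcripts if t.gene_id not in sites],
    )
    libraries = {}
    for cond, kid in zip(conditions, kids[2:]):
        lib, prov = simulate_tag_library(
            transcripts, abundance[cond], cfg, np.random.default_rng(kid), cond
        )
        libraries[cond] = lib
        truth.provenance[cond] = prov
    return SimulatedExperiment(transcripts=transcripts, truth=truth, libraries=libraries)
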