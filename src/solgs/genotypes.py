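"""Genotype containers, quality control, LD-based tag-SNP selection and PCA.

The central object is :class:`GenotypeMatrix`, an accessions x SNPs matrix of
alternate-allele dosages (0/1/2, with ``MISSING = -1`` for no-calls) plus a
chromosome/position map and optional per-accession metadata (species label,
cultivated/wild flag).  The QC pipeline mirrors a standard genotyping-by-
sequencing workflow: missingness filter, modal imputation, minor-allele-
frequency filter and near-duplicate pruning at very high r2, followed by
LD-based selection of a ranked set of tag SNPs.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing dosage call.
MISSING = -1

_VALID_DOSAGES = frozenset({0, 1, 2, MISSING})


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs dosage matrix with variant map and accession metadata.

    Parameters
    ----------
    accession_ids
        Ordered unique accession identifiers (rows).
    variant_ids
        Ordered unique variant identifiers (columns).
    chrom
        Per-variant chromosome label.
    pos
        Per-variant 1-based coordinate; strictly increasing within chromosome.
    dosage
        ``(n_accessions, n_variants)`` integer array in {0, 1, 2, MISSING}.
    meta
        Optional per-accession table indexed by accession id with columns
        ``species`` (str) and ``is_wild`` (bool).
    ref, alt
        Per-variant reference / alternate alleles (single bases); kept so a
        matrix read from VCF round-trips.
    """

    accession_ids: np.ndarray
    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    meta: pd.DataFrame | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.accession_ids = np.asarray(self.accession_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if len(self.accession_ids) != n or len(self.variant_ids) != m:
            raise ValueError("dosage shape inconsistent with id vectors")
        if len(self.chrom) != m or len(self.pos) != m:
            raise ValueError("variant map length inconsistent")
        if len(set(self.accession_ids)) != n:
            raise ValueError("accession ids not unique")
        if len(set(self.variant_ids)) != m:
            raise ValueError("variant ids not unique")
        vals = set(np.unique(self.dosage).tolist())
        if not vals <= _VALID_DOSAGES:
            raise ValueError(f"dosage values outside {{0,1,2,{MISSING}}}: {vals - _VALID_DOSAGES}")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        if self.ref is None:
            self.ref = np.full(m, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(m, "T", dtype=object)

    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def is_complete(self) -> bool:
        return not np.any(self.dosage == MISSING)

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the variants at ``index`` (order preserved by caller)."""
        index = np.asarray(index)
        return replace(
            self,
            variant_ids=self.variant_ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            dosage=self.dosage[:, index],
            ref=self.ref[index],
            alt=self.alt[index],
        )

    def take_accessions(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        meta = None
        if self.meta is not None:
            meta = self.meta.loc[self.accession_ids[index]]
        return replace(
            self,
            accession_ids=self.accession_ids[index],
            dosage=self.dosage[index, :],
            meta=meta,
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.accession_ids, other.accession_ids)
            and np.array_equal(self.variant_ids, other.variant_ids)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass
class TagSelection:
    """Ranked tag SNPs and the redundancy map produced by greedy tagging.

    ``tag_ids`` is importance-ranked: per-chromosome tags are ordered by
    selection step (how many then-uncovered SNPs they covered) and the
    per-chromosome lists are interleaved rank-by-rank so that any prefix is
    genome-wide representative.  ``covered_by`` maps every non-tag variant to
    the same-chromosome tag that covers it at ``r2 >= r2_threshold``.
    """

    tag_ids: list
    covered_by: dict
    r2_threshold: float
    n_covered: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# VCF and delimited I/O
# ---------------------------------------------------------------------------

_GT_TYPE_TO_DOSAGE = {0: 0, 1: 1, 3: 2, 2: MISSING}  # cyvcf2 gt_types coding


def read_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a dosage matrix.

    Diploid GT fields are mapped to alternate-allele counts; missing
    genotypes become :data:`MISSING`.  Multi-allelic or non-SNP records are
    skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    cols, vids, chroms, poss, refs, alts = [], [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            n_skipped += 1
            continue
        cols.append([_GT_TYPE_TO_DOSAGE[t] for t in v.gt_types])
        vids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    dosage = np.asarray(cols, dtype=np.int8).T if cols else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(
        accession_ids=samples,
        variant_ids=np.asarray(vids, dtype=object),
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        dosage=dosage,
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
    )


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write the matrix as an uncompressed VCF (GT only, 1-based positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(G.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(a) for a in G.accession_ids) + "\n")
        for j in range(G.n_variants):
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in G.dosage[:, j])
            fh.write(
                f"{G.chrom[j]}\t{G.pos[j]}\t{G.variant_ids[j]}\t{G.ref[j]}\t{G.alt[j]}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def write_dosage(G: GenotypeMatrix, matrix_path: str, map_path: str, meta_path: str | None = None) -> None:
    """Write a delimited dosage matrix plus a 4-column variant map."""
    pd.DataFrame(G.dosage, index=G.accession_ids, columns=G.variant_ids).to_csv(
        matrix_path, sep="\t", index_label="accession"
    )
    pd.DataFrame(
        {"id": G.variant_ids, "chrom": G.chrom, "pos": G.pos,
         "alleles": [f"{r}/{a}" for r, a in zip(G.ref, G.alt)]}
    ).to_csv(map_path, sep="\t", index=False)
    if meta_path is not None and G.meta is not None:
        G.meta.to_csv(meta_path, sep="\t", index_label="accession")


def read_dosage(matrix_path: str, map_path: str, meta_path: str | None = None) -> GenotypeMatrix:
    mat = pd.read_csv(matrix_path, sep="\t", index_col="accession")
    vmap = pd.read_csv(map_path, sep="\t")
    alleles = vmap["alleles"].str.split("/", expand=True)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col="accession")
        meta["is_wild"] = meta["is_wild"].astype(bool)
    return GenotypeMatrix(
        accession_ids=mat.index.to_numpy(dtype=object),
        variant_ids=vmap["id"].to_numpy(dtype=object).astype(str).astype(object),
        chrom=vmap["chrom"].to_numpy(dtype=object).astype(str).astype(object),
        pos=vmap["pos"].to_numpy(),
        dosage=mat.to_numpy(dtype=np.int8),
        meta=meta,
        ref=alleles[0].to_numpy(dtype=object),
        alt=alleles[1].to_numpy(dtype=object),
    )


def write_tag_selection(sel: TagSelection, path: str) -> None:
    pd.DataFrame(
        {"tag_id": sel.tag_ids,
         "rank": np.arange(len(sel.tag_ids)),
         "n_covered": [sel.n_covered.get(t, 0) for t in sel.tag_ids]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def filter_missingness(G: GenotypeMatrix, max_missing: float = 0.5) -> GenotypeMatrix:
    """Drop variants whose missing-call fraction exceeds ``max_missing``.

    The boundary is kept: a variant missing in exactly ``max_missing`` of
    accessions is retained ("at most" semantics).
    """
    frac = np.mean(G.dosage == MISSING, axis=0)
    keep = np.flatnonzero(frac <= max_missing)
    if keep.size == 0:
        logger.warning("filter_missingness: no variants retained")
    return G.take_variants(keep)


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the per-variant modal dosage (ties -> lower)."""
    dosage = G.dosage.copy()
    miss = dosage == MISSING
    cols = np.flatnonzero(miss.any(axis=0))
    for j in cols:
        obs = dosage[~miss[:, j], j]
        if obs.size == 0:
            raise ValueError(f"variant {G.variant_ids[j]} has no observed calls")
        counts = np.bincount(obs, minlength=3)
        dosage[miss[:, j], j] = int(np.argmax(counts))  # first max -> lower dosage
    return replace(G, dosage=dosage)


def allele_frequency(G: GenotypeMatrix) -> np.ndarray:
    """Alternate-allele frequency per variant, computed on observed calls."""
    d = G.dosage.astype(float)
    obs = d != MISSING
    d[~obs] = 0.0
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        raise ValueError("variant with no observed calls")
    return d.sum(axis=0) / (2.0 * n_obs)


def filter_maf(G: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Drop variants with minor allele frequency strictly below ``min_maf``."""
    p = allele_frequency(G)
    maf = np.minimum(p, 1.0 - p)
    return G.take_variants(np.flatnonzero(maf >= min_maf))


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def _standardized(dosage: np.ndarray) -> np.ndarray:
    """Column-standardized dosage; zero-variance columns map to all-zeros."""
    X = dosage.astype(float)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    nz = sd > 0
    X[:, nz] /= sd[nz]
    X[:, ~nz] = 0.0
    return X


def ld_r2(G: GenotypeMatrix, i: int, j: int) -> float:
    """Composite LD between variants ``i`` and ``j``: squared Pearson
    correlation of dosage vectors (phase-free)."""
    x = G.dosage[:, i].astype(float)
    y = G.dosage[:, j].astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("ld_r2 requires polymorphic variants")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def prune_redundant(G: GenotypeMatrix, r2: float = 0.999, window_snps: int = 100) -> GenotypeMatrix:
    """Greedy left-to-right removal of near-duplicate variants.

    Within each chromosome a variant is dropped when its r2 with any
    previously retained variant inside a sliding window of ``window_snps``
    positions reaches ``r2``.
    """
    if not G.is_complete:
        raise ValueError("prune_redundant requires a complete matrix")
    keep_global: list[int] = []
    for c in pd.unique(G.chrom):
        idx = np.flatnonzero(G.chrom == c)
        X = _standardized(G.dosage[:, idx])
        n = X.shape[0]
        kept: list[int] = []
        for local in range(len(idx)):
            drop = False
            for k in reversed(kept):
                if local - k > window_snps:
                    break
                r = float(X[:, k] @ X[:, local]) / n
                if r * r >= r2:
                    drop = True
                    break
            if not drop:
                kept.append(local)
        keep_global.extend(idx[kept])
    keep_global.sort()
    n_dropped = G.n_variants - len(keep_global)
    if n_dropped:
        logger.info("prune_redundant: dropped %d variants at r2 >= %g", n_dropped, r2)
    return G.take_variants(np.asarray(keep_global, dtype=int))


def _window_neighbors(X: np.ndarray, window: int, r2_thr: float) -> list[set]:
    """Per-column sets of window-local columns with r2 >= threshold (incl self)."""
    n, m = X.shape
    nbrs: list[set] = [{j} for j in range(m)]
    for d in range(1, min(window, m - 1) + 1):
        r = np.einsum("ij,ij->j", X[:, :-d], X[:, d:]) / n
        hit = np.flatnonzero(r * r >= r2_thr)
        for a in hit:
            nbrs[a].add(a + d)
            nbrs[a + d].add(a)
    return nbrs


def select_tag_snps(G: GenotypeMatrix, r2_tag: float = 0.8, window_snps: int = 100) -> TagSelection:
    """Greedy maximum-coverage tag-SNP selection per chromosome.

    Repeatedly picks the not-yet-covered variant whose window-local
    neighborhood (r2 >= ``r2_tag``) contains the most uncovered variants
    (ties broken by lower position), marks it as a tag and its neighborhood
    as covered, until every variant is covered.  Per-chromosome tag lists
    are interleaved rank-by-rank into the genome-wide ranking.
    """
    if not G.is_complete:
        raise ValueError("select_tag_snps requires a complete matrix")
    per_chrom_tags: list[list[int]] = []
    covered_by: dict = {}
    n_covered: dict = {}
    for c in pd.unique(G.chrom):
        idx = np.flatnonzero(G.chrom == c)
        X = _standardized(G.dosage[:, idx])
        nbrs = _window_neighbors(X, window_snps, r2_tag)
        m = len(idx)
        covered = np.zeros(m, dtype=bool)
        pos = G.pos[idx]
        # lazy greedy: heap of (-count, pos, local index) with stale counts
        heap = [(-len(nbrs[j]), int(pos[j]), j) for j in range(m)]
        heapq.heapify(heap)
        tags: list[int] = []
        n_left = m
        while n_left > 0:
            neg_cnt, p, j = heapq.heappop(heap)
            if covered[j]:
                continue
            cnt = sum(1 for k in nbrs[j] if not covered[k])
            if -neg_cnt != cnt:
                heapq.heappush(heap, (-cnt, p, j))
                continue
            tags.append(j)
            tid = G.variant_ids[idx[j]]
            n_cov = 0
            for k in nbrs[j]:
                if not covered[k]:
                    covered[k] = True
                    n_left -= 1
                    n_cov += 1
                    if k != j:
                        covered_by[G.variant_ids[idx[k]]] = tid
            n_covered[tid] = n_cov
        per_chrom_tags.append([G.variant_ids[idx[j]] for j in tags])
    # interleave per-chromosome rankings so prefixes span the genome
    tag_ids: list = []
    max_rank = max((len(t) for t in per_chrom_tags), default=0)
    for r in range(max_rank):
        for tags in per_chrom_tags:
            if r < len(tags):
                tag_ids.append(tags[r])
    return TagSelection(tag_ids=tag_ids, covered_by=covered_by,
                        r2_threshold=r2_tag, n_covered=n_covered)


def tag_subset(sel: TagSelection, fraction: float) -> list:
    """First ``ceil(fraction * n_tags)`` tags in rank order (nested subsets)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = int(np.ceil(fraction * len(sel.tag_ids)))
    return sel.tag_ids[:k]


# ---------------------------------------------------------------------------
# Population structure
# ---------------------------------------------------------------------------


def pca(G: GenotypeMatrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the centered, unit-variance-scaled dosage matrix via SVD.

    Monomorphic columns are dropped before scaling.  Returns per-accession
    scores (n x k) and the explained variance of each component
    (non-increasing).
    """
    if not G.is_complete:
        raise ValueError("pca requires a complete matrix")
    X = G.dosage.astype(float)
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    if k >= min(X.shape):
        raise ValueError(f"k={k} too large for matrix of shape {X.shape}")
    X -= X.mean(axis=0)
    X /= X.std(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * s[:k]
    explained = s[:k] ** 2 / (G.n_accessions - 1)
    return scores, explained
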