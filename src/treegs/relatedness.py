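"""Pedigree and genomic relationship matrices.

The additive ("numerator") relationship matrix A is built from the pedigree with
the tabular method, which tracks inbreeding exactly:

    a(i,i) = 1 + 0.5 * a(m_i, f_i)
    a(i,j) = 0.5 * (a(j, m_i) + a(j, f_i))   for j already processed

with founders (unknown parents) treated as unrelated and non-inbred.  The genomic
relationship matrix G follows VanRaden's first method,

    G = Z Z' / (2 * sum_k p_k (1 - p_k)),   Z = M - 2p,

where M holds 0/1/2 dosages and p the observed allele frequencies.  diag(A) and
diag(G) equal 1 + F, so per-individual inbreeding coefficients come for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "GenotypeMatrix",
    "build_A",
    "build_A_inverse",
    "build_G",
    "blend",
]

UNKNOWN = ""


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Ordered pedigree records; parents must be sortable ahead of offspring."""

    ids: list[str]
    mothers: list[str]
    fathers: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.mothers) or len(self.ids) != len(self.fathers):
            raise PedigreeError("ids, mothers and fathers must have equal length")
        if len(set(self.ids)) != len(self.ids):
            dup = pd.Series(self.ids).value_counts()
            raise PedigreeError(f"duplicate identities: {list(dup[dup > 1].index)}")

    def __len__(self) -> int:
        return len(self.ids)

    def sorted(self) -> "Pedigree":
        """Topologically sort so every parent precedes its offspring.

        Raises on pedigree cycles (an individual that is its own ancestor).
        """
        parents = {
            i: tuple(p for p in (m, f) if p != UNKNOWN)
            for i, m, f in zip(self.ids, self.mothers, self.fathers)
        }
        order: list[str] = []
        state: dict[str, int] = {}  # 0 in progress, 1 done

        for root in self.ids:
            if state.get(root) == 1:
                continue
            stack = [(root, iter(parents.get(root, ())))]
            state[root] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for par in it:
                    if par not in parents:
                        continue  # parent not a record: treated as founder
                    s = state.get(par)
                    if s == 0:
                        cycle = [n for n, _ in stack]
                        raise PedigreeError(f"pedigree cycle involving {par!r}: {cycle}")
                    if s is None:
                        stack.append((par, iter(parents[par])))
                        state[par] = 0
                        advanced = True
                        break
                if not advanced:
                    stack.pop()
                    state[node] = 1
                    order.append(node)
        lut = {i: (m, f) for i, m, f in zip(self.ids, self.mothers, self.fathers)}
        return Pedigree(
            ids=order,
            mothers=[lut[i][0] for i in order],
            fathers=[lut[i][1] for i in order],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "mother": self.mothers, "father": self.fathers})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        df = df.fillna(UNKNOWN)
        return cls(
            ids=[str(i) for i in df["id"]],
            mothers=[str(m) for m in df["mother"]],
            fathers=[str(f) for f in df["father"]],
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, dtype=str, keep_default_na=False))


@dataclass
class RelationshipMatrix:
    """Square symmetric relationship matrix over an ordered id list."""

    ids: list[str]
    values: np.ndarray
    kind: str  # A | A_inverse | G | G_blended

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")

    @property
    def index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}

    def inbreeding(self) -> pd.Series:
        """F = diag - 1 (meaningful for kinds A and G)."""
        return pd.Series(np.diag(self.values) - 1.0, index=self.ids, name="F")

    def submatrix(self, ids: list[str]) -> "RelationshipMatrix":
        idx = self.index
        sel = np.array([idx[i] for i in ids])
        return RelationshipMatrix(list(ids), self.values[np.ix_(sel, sel)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")

    def write_triplets(self, path) -> None:
        ii, jj = np.nonzero(self.values)
        keep = ii <= jj
        pd.DataFrame(
            {
                "id_i": [self.ids[i] for i in ii[keep]],
                "id_j": [self.ids[j] for j in jj[keep]],
                "value": self.values[ii[keep], jj[keep]],
            }
        ).to_csv(path, index=False, float_format="%.10g")


@dataclass
class GenotypeMatrix:
    """Individuals x SNP dosage matrix in {0,1,2}, NaN marking missing calls."""

    ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape does not match id/snp lists")
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def row(self, individual: str) -> np.ndarray:
        return self.dosages[self._index[individual]]

    def allele_frequencies(self) -> np.ndarray:
        """Observed frequency of the counted allele per SNP (missing ignored)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, ids: list[str]) -> "GenotypeMatrix":
        sel = [self._index[i] for i in ids]
        return GenotypeMatrix(list(ids), list(self.snp_ids), self.dosages[sel])

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages, index=self.ids, columns=self.snp_ids)
        df.index.name = "id"
        df.to_csv(path, sep="\t", float_format="%g")

    @classmethod
    def read_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy(dtype=float))

    def write_vcf(self, path, chrom: str = "1") -> None:
        """Minimal diploid unphased VCF (GT only); missing written as ./."""
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(self.ids) + "\n")
            for k, snp in enumerate(self.snp_ids):
                calls = [
                    gt_codes.get(d, "./.") if np.isfinite(d) else "./."
                    for d in self.dosages[:, k]
                ]
                fh.write(f"{chrom}\t{k + 1}\t{snp}\tA\tC\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")

    @classmethod
    def read_vcf(cls, path) -> "GenotypeMatrix":
        ids: list[str] = []
        snp_ids: list[str] = []
        rows: list[list[float]] = []
        code = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    ids = parts[9:]
                    continue
                snp_ids.append(parts[2])
                fmt = parts[8].split(":")
                gi = fmt.index("GT")
                rows.append(
                    [code.get(c.split(":")[gi].replace("|", "/"), np.nan) for c in parts[9:]]
                )
        return cls(ids, snp_ids, np.array(rows, dtype=float).T)


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Unknown parents are treated as unrelated, non-inbred founders.  The result's
    diagonal is 1 + F.
    """
    ped = pedigree.sorted()
    n = len(ped)
    idx = {i: k for k, i in enumerate(ped.ids)}
    # parent column indices, -1 = unknown/not in pedigree
    mi = np.array([idx.get(m, -1) for m in ped.mothers])
    fi = np.array([idx.get(f, -1) for f in ped.fathers])
    A = np.zeros((n, n))
    for k in range(n):
        m, f = mi[k], fi[k]
        if k > 0:
            row = np.zeros(k)
            if m >= 0:
                row += 0.5 * A[m, :k]
            if f >= 0:
                row += 0.5 * A[f, :k]
            A[k, :k] = row
            A[:k, k] = row
        amf = A[m, f] if (m >= 0 and f >= 0) else 0.0
        A[k, k] = 1.0 + 0.5 * amf
    # restore caller's ordering
    order = np.array([idx[i] for i in pedigree.ids])
    return RelationshipMatrix(list(pedigree.ids), A[np.ix_(order, order)], "A")


def build_A_inverse(pedigree: Pedigree) -> RelationshipMatrix:
    """Inverse numerator relationship matrix (Cholesky-based direct inverse)."""
    A = build_A(pedigree)
    try:
        c = np.linalg.cholesky(A.values)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise PedigreeError(f"A matrix is singular or indefinite: {exc}") from exc
    cinv = np.linalg.inv(c)
    return RelationshipMatrix(list(A.ids), cinv.T @ cinv, "A_inverse")


def build_G(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    log: list | None = None,
) -> RelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    Monomorphic SNPs and SNPs with minor allele frequency below ``maf_min`` are
    excluded; missing dosages are mean-imputed per SNP before centering.  Allele
    frequencies are estimated from the genotyped sample itself.
    """
    if genotypes.n_individuals < 2:
        raise ValueError("need at least two genotyped individuals")
    M = genotypes.dosages.copy()
    p = np.nanmean(M, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    n_dropped = int((~keep).sum())
    if log is not None:
        log.append(f"build_G: dropped {n_dropped} SNPs with MAF < {maf_min} (of {M.shape[1]})")
    if not keep.any():
        raise ValueError("all SNPs filtered out (monomorphic or below MAF threshold)")
    M = M[:, keep]
    p = p[keep]
    # mean imputation of missing dosages
    miss = ~np.isfinite(M)
    if miss.any():
        M[miss] = np.broadcast_to(2.0 * p, M.shape)[miss]
        if log is not None:
            log.append(f"build_G: mean-imputed {int(miss.sum())} missing dosages")
    Z = M - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(list(genotypes.ids), G, "G")


def blend(
    G: RelationshipMatrix,
    weight: float = 0.01,
    target: RelationshipMatrix | None = None,
) -> RelationshipMatrix:
    """Blend (1-w)*G + w*target (identity by default) and verify positive definiteness."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError("blend weight must be in [0, 1]")
    T = np.eye(len(G.ids)) if target is None else target.submatrix(G.ids).values
    B = (1.0 - weight) * G.values + weight * T
    try:
        np.linalg.cholesky(B)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"blended matrix not positive definite at weight {weight}; increase the weight"
        ) from exc
    return RelationshipMatrix(list(G.ids), B, "G_blended")
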