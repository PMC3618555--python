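"""Genotype/phenotype containers, inheritance-model encoding, and imputation.

Genotypes are stored as minor-allele dosages: 0 = homozygous major,
1 = heterozygous, 2 = homozygous minor, with :data:`MISSING` (-1) marking
sporadically missing calls.  All odds ratios downstream are therefore
expressed relative to major-allele carriers.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call inside the dosage grid.
MISSING: int = -1


class ModelCode(enum.Enum):
    """Inheritance model used to code a SNP's dosage for regression."""

    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    ADDITIVE = "additive"


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for one biallelic SNP."""

    snp_id: str
    chromosome: str = "0"
    gene_symbol: str | None = None
    major_allele: str = "A"
    minor_allele: str = "G"

    def __post_init__(self) -> None:
        if self.major_allele == self.minor_allele:
            raise ValueError(
                f"{self.snp_id}: major and minor allele must differ "
                f"(both {self.major_allele!r})"
            )

    def genotype_label(self, dosage: int) -> str:
        """Render a dosage as an allele-pair string, e.g. 0 -> 'AA', 1 -> 'AG'."""
        a, b = self.major_allele, self.minor_allele
        return {0: a + a, 1: a + b, 2: b + b}[int(dosage)]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix with SNP metadata."""

    subject_ids: list[str]
    snps: list[SnpRecord]
    dosage: np.ndarray  # int8, values in {0,1,2} or MISSING

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.subject_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"dosage contains values outside {{0,1,2,MISSING}}: "
                             f"{np.unique(self.dosage[bad])}")
        ids = self.snp_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in GenotypeMatrix")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in matrix") from None

    def record(self, snp_id: str) -> SnpRecord:
        return self.snps[self.snp_index(snp_id)]

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self.snp_index(snp_id)]

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return (self.dosage == MISSING).mean(axis=0)

    def has_missing(self) -> bool:
        return bool((self.dosage == MISSING).any())

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(
            subject_ids=list(self.subject_ids),
            snps=[self.snps[i] for i in idx],
            dosage=self.dosage[:, idx].copy(),
        )

    def subset_subjects(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = list(rows)
        return GenotypeMatrix(
            subject_ids=[self.subject_ids[i] for i in rows],
            snps=list(self.snps),
            dosage=self.dosage[rows, :].copy(),
        )


@dataclass
class Phenotype:
    """Binary outcome per subject (1 = aggressive disease)."""

    subject_ids: list[str]
    aggressive: np.ndarray

    def __post_init__(self) -> None:
        self.aggressive = np.asarray(self.aggressive, dtype=np.int8)
        if self.aggressive.shape != (len(self.subject_ids),):
            raise ValueError("phenotype length does not match subject_ids")
        if not set(np.unique(self.aggressive)) <= {0, 1}:
            raise ValueError("aggressive must be coded 0/1")
        if len(np.unique(self.aggressive)) < 2:
            raise ValueError("both outcome classes must be non-empty")

    @property
    def y(self) -> np.ndarray:
        return self.aggressive

    def subset(self, rows: Sequence[int]) -> "Phenotype":
        rows = list(rows)
        return Phenotype(
            subject_ids=[self.subject_ids[i] for i in rows],
            aggressive=self.aggressive[rows].copy(),
        )


# ---------------------------------------------------------------------------
# Encoding and imputation
# ---------------------------------------------------------------------------

def encode_snp(dosages: np.ndarray, model: ModelCode) -> np.ndarray:
    """Code a dosage vector under an inheritance model.

    DOMINANT -> 1 if at least one minor allele; RECESSIVE -> 1 only for
    homozygous minor; ADDITIVE -> dosage unchanged (per-allele trend).
    Missing values must be imputed first.
    """
    d = np.asarray(dosages)
    if (d == MISSING).any():
        raise ValueError("dosage vector contains missing values; run impute_missing first")
    if model is ModelCode.DOMINANT:
        return (d >= 1).astype(np.int8)
    if model is ModelCode.RECESSIVE:
        return (d == 2).astype(np.int8)
    if model is ModelCode.ADDITIVE:
        return d.astype(np.int8)
    raise ValueError(f"unknown model {model!r}")


def impute_missing(gm: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Replace missing calls with the per-SNP modal genotype.

    Modal ties are resolved by sampling from the SNP's empirical genotype
    frequencies with the given seed, so the output is reproducible.
    Observed cells are never changed; complete matrices pass through
    unaltered (idempotence).
    """
    if not gm.has_missing():
        return gm
    rng = np.random.default_rng(seed)
    dosage = gm.dosage.copy()
    for j in range(gm.n_snps):
        col = dosage[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValueError(f"SNP {gm.snps[j].snp_id} has no observed genotypes")
        counts = np.bincount(obs, minlength=3)
        top = counts.max()
        modes = np.flatnonzero(counts == top)
        if modes.size == 1:
            fill = np.full(miss.sum(), modes[0], dtype=np.int8)
        else:
            probs = counts / counts.sum()
            fill = rng.choice(3, size=miss.sum(), p=probs).astype(np.int8)
        col[miss] = fill
    out = GenotypeMatrix(list(gm.subject_ids), list(gm.snps), dosage)
    assert not out.has_missing()
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _orient_minor(dosage: np.ndarray, snp: SnpRecord) -> tuple[np.ndarray, SnpRecord]:
    """Flip dosage so that 2 codes the in-sample minor allele.

    An exact 0.5 allele frequency is broken lexicographically (the
    alphabetically first allele becomes the major allele) and logged.
    """
    obs = dosage[dosage != MISSING]
    if obs.size == 0:
        return dosage, snp
    freq_minor = obs.mean() / 2.0
    flip = False
    if freq_minor > 0.5:
        flip = True
    elif freq_minor == 0.5 and snp.minor_allele < snp.major_allele:
        flip = True
        logger.info("SNP %s allele frequency exactly 0.5; tie broken "
                    "lexicographically", snp.snp_id)
    if flip:
        out = dosage.copy()
        nz = out != MISSING
        out[nz] = 2 - out[nz]
        snp = replace(snp, major_allele=snp.minor_allele, minor_allele=snp.major_allele)
        return out, snp
    return dosage, snp


def load_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the canonical TSV dialect: header ``subject_id<TAB>rs1<TAB>...``,
    cell values in {0,1,2,NA}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "subject_id":
        raise ValueError(f"{path}: first column must be 'subject_id', got "
                         f"{df.columns[0]!r}")
    subject_ids = df["subject_id"].astype(str).tolist()
    snp_ids = list(df.columns[1:])
    grid = np.full((len(subject_ids), len(snp_ids)), MISSING, dtype=np.int8)
    for j, sid in enumerate(snp_ids):
        col = df[sid]
        ok = col.notna() & (col != "NA")
        try:
            grid[ok.to_numpy(), j] = col[ok].astype(int).to_numpy()
        except ValueError as exc:
            raise ValueError(f"{path}: column {sid!r} has a non-integer "
                             f"genotype value") from exc
    snps = [SnpRecord(snp_id=s) for s in snp_ids]
    return GenotypeMatrix(subject_ids, snps, grid)


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path,
                        sidecar: str | Path | None = None) -> None:
    """Write the canonical TSV dosage matrix plus an optional JSON sidecar
    of SNP records."""
    df = pd.DataFrame(gm.dosage.astype(object), columns=gm.snp_ids)
    df = df.mask(df == MISSING, "NA")
    df.insert(0, "subject_id", gm.subject_ids)
    df.to_csv(path, sep="\t", index=False)
    if sidecar is not None:
        recs = [
            {"snp_id": s.snp_id, "chromosome": s.chromosome,
             "gene_symbol": s.gene_symbol, "major_allele": s.major_allele,
             "minor_allele": s.minor_allele}
            for s in gm.snps
        ]
        Path(sidecar).write_text(json.dumps(recs, indent=1))


def load_snp_sidecar(gm: GenotypeMatrix, path: str | Path) -> GenotypeMatrix:
    """Attach SNP metadata from a JSON sidecar to a loaded TSV matrix."""
    recs = {r["snp_id"]: r for r in json.loads(Path(path).read_text())}
    snps = []
    for s in gm.snps:
        r = recs.get(s.snp_id)
        if r is None:
            snps.append(s)
        else:
            snps.append(SnpRecord(
                snp_id=r["snp_id"], chromosome=str(r.get("chromosome", "0")),
                gene_symbol=r.get("gene_symbol"),
                major_allele=r.get("major_allele", "A"),
                minor_allele=r.get("minor_allele", "G"),
            ))
    return GenotypeMatrix(list(gm.subject_ids), snps, gm.dosage.copy())


def load_genotypes_vcf(path: str | Path) -> tuple[GenotypeMatrix, list[str]]:
    """Read biallelic SNPs from a VCF (GT field).

    ALT dosage is re-oriented to minor-allele dosage by in-sample frequency.
    Multi-allelic sites are rejected and returned in the exclusion report.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires cyvcf2 (install trmscan[vcf])") from exc
    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    cols: list[np.ndarray] = []
    snps: list[SnpRecord] = []
    excluded: list[str] = []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            excluded.append(vid)
            continue
        gt = np.asarray(var.gt_types)  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        dos = np.where(gt == 0, 0, np.where(gt == 1, 1,
                       np.where(gt == 3, 2, MISSING))).astype(np.int8)
        rec = SnpRecord(snp_id=vid, chromosome=str(var.CHROM),
                        major_allele=var.REF, minor_allele=var.ALT[0])
        dos, rec = _orient_minor(dos, rec)
        cols.append(dos)
        snps.append(rec)
    if excluded:
        logger.warning("excluded %d multi-allelic/non-SNP sites", len(excluded))
    grid = (np.stack(cols, axis=1) if cols
            else np.empty((len(subject_ids), 0), dtype=np.int8))
    return GenotypeMatrix(subject_ids, snps, grid), excluded


def load_genotypes_ped(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a PLINK text .ped/.map pair (biallelic SNPs, '0' = missing allele)."""
    map_df = pd.read_csv(map_path, sep=r"\s+", header=None,
                         names=["chrom", "snp_id", "cm", "pos"], dtype=str)
    snp_ids = map_df["snp_id"].tolist()
    n_snps = len(snp_ids)
    subject_ids: list[str] = []
    rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(f"{ped_path}: line {ln} has {len(parts)} fields, "
                                 f"expected {6 + 2 * n_snps}")
            subject_ids.append(parts[1])
            alleles = parts[6:]
            rows.append([(alleles[2 * j], alleles[2 * j + 1]) for j in range(n_snps)])
    grid = np.full((len(subject_ids), n_snps), MISSING, dtype=np.int8)
    snps: list[SnpRecord] = []
    for j in range(n_snps):
        col_pairs = [r[j] for r in rows]
        seen = sorted({a for p in col_pairs for a in p if a != "0"})
        if len(seen) > 2:
            raise ValueError(f"SNP {snp_ids[j]} has >2 alleles: {seen}")
        if not seen:
            seen = ["A"]
        a1 = seen[0]
        counts = {a: 0 for a in seen}
        for p in col_pairs:
            for a in p:
                if a != "0":
                    counts[a] += 1
        # provisional: count copies of the lexicographically last allele
        alt = seen[-1] if len(seen) == 2 else a1
        for i, (x, y) in enumerate(col_pairs):
            if x == "0" or y == "0":
                continue
            grid[i, j] = (x == alt) + (y == alt)
        major = seen[0] if len(seen) == 2 else a1
        rec = SnpRecord(snp_id=snp_ids[j], chromosome=map_df["chrom"][j],
                        major_allele=major,
                        minor_allele=alt if len(seen) == 2 else ("G" if alt != "G" else "T"))
        dos, rec = _orient_minor(grid[:, j], rec)
        grid[:, j] = dos
        snps.append(rec)
    return GenotypeMatrix(subject_ids, snps, grid)


def load_genotypes(path: str | Path, format: str,
                   map_path: str | Path | None = None) -> GenotypeMatrix:
    """Dispatch loader over the supported formats: 'tsv', 'vcf', 'ped'."""
    if format == "tsv":
        return load_genotypes_tsv(path)
    if format == "vcf":
        gm, _ = load_genotypes_vcf(path)
        return gm
    if format == "ped":
        if map_path is None:
            p = Path(path)
            map_path = p.with_suffix(".map")
        return load_genotypes_ped(path, map_path)
    raise ValueError(f"unknown genotype format {format!r}")


def load_phenotype_tsv(path: str | Path) -> Phenotype:
    """Read the phenotype TSV: columns ``subject_id`` and ``aggressive`` (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    for col in ("subject_id", "aggressive"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return Phenotype(df["subject_id"].tolist(),
                     df["aggressive"].to_numpy(dtype=np.int8))


def align(gm: GenotypeMatrix, phen: Phenotype) -> tuple[GenotypeMatrix, Phenotype]:
    """Restrict both objects to shared subjects, in genotype-matrix order."""
    pheno_idx = {s: i for i, s in enumerate(phen.subject_ids)}
    rows_g, rows_p = [], []
    for i, s in enumerate(gm.subject_ids):
        if s in pheno_idx:
            rows_g.append(i)
            rows_p.append(pheno_idx[s])
    if not rows_g:
        raise ValueError("no shared subjects between genotypes and phenotype")
    return gm.subset_subjects(rows_g), phen.subset(rows_p)
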