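"""Genotype, phenotype and SNP-set input handling.

Genotypes are held as a sample x variant matrix of minor-allele dosages.
Two on-disk dialects are supported: VCF 4.2 (GT field only, diploid
biallelic sites) and a plain TSV table (first column sample ID, one column
per variant, values 0/1/2 or NA).  At load time every variant is oriented
to its minor allele (dosages flipped when the alternate-allele frequency
exceeds 0.5) so that MAF-based weighting and the rare/common partition are
well defined downstream.  Missing genotypes are resolved at ingest, by
default with the variant's observed dosage mean — the standard choice in
rare-variant testing because it preserves the allele frequency; a
complete-case policy is available.

Phenotypes arrive as a TSV with named trait / environment / covariate
columns.  A continuous environment is mean-centered by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "SampleTable",
    "SnpSet",
    "compute_maf",
    "load_genotypes",
    "load_genotype_table",
    "write_genotype_table",
    "load_sample_table",
    "read_snp_sets",
    "align_samples",
]


def compute_maf(column: np.ndarray) -> float:
    """Minor-allele frequency of one dosage column, folded into [0, 0.5].

    ``f = sum(dosages) / (2n)`` is the frequency of the counted allele;
    the folded value ``min(f, 1 - f)`` is returned so orientation does
    not matter.  Mean-imputed (fractional) dosages are accepted.
    """
    col = np.asarray(column, dtype=float)
    if col.size == 0:
        raise ValueError("cannot compute MAF of an empty column")
    if np.isnan(col).any():
        raise ValueError("MAF undefined with unresolved missing genotypes")
    f = float(col.sum()) / (2.0 * col.size)
    return min(f, 1.0 - f)


@dataclass
class SnpSet:
    """A named group of variants tested jointly (a gene or pathway region).

    Either an explicit list of variant identifiers or a 1-based inclusive
    genomic region resolved against the VCF at load time.
    """

    name: str
    variant_ids: list[str] | None = None
    region: tuple[str, int, int] | None = None  # (chrom, start, end), 1-based inclusive

    def __post_init__(self) -> None:
        if (self.variant_ids is None) == (self.region is None):
            raise ValueError(f"SNP set {self.name!r}: give variant_ids or region, not both")


@dataclass
class GenotypeMatrix:
    """Sample x variant minor-allele dosages with variant metadata.

    ``counts`` is n x M float; observed entries are 0/1/2, mean-imputed
    entries may be fractional.  ``flipped`` records which variants were
    re-oriented to the minor allele at load time.
    """

    samples: list[str]
    variant_ids: list[str]
    counts: np.ndarray
    chrom: list[str] | None = None
    pos: np.ndarray | None = None
    flipped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n, m = self.counts.shape
        if n != len(self.samples) or m != len(self.variant_ids):
            raise ValueError("counts shape does not match sample/variant metadata")
        if self.flipped is None:
            self.flipped = np.zeros(m, dtype=bool)
        obs = self.counts[~np.isnan(self.counts)]
        if obs.size and (np.nanmin(self.counts) < 0 or np.nanmax(self.counts) > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    def mafs(self) -> np.ndarray:
        """Folded MAF of every variant, each in [0, 0.5]."""
        return np.array([compute_maf(self.counts[:, j]) for j in range(self.m)])

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variant_ids=list(self.variant_ids),
            counts=self.counts[idx],
            chrom=self.chrom,
            pos=self.pos,
            flipped=self.flipped,
        )


@dataclass
class SampleTable:
    """Per-sample trait, environment and confounder covariates.

    ``trait_kind`` selects the link of the adjustment model downstream:
    identity for a continuous trait, logit for a binary one.
    """

    samples: list[str]
    y: np.ndarray
    env: np.ndarray
    covariates: np.ndarray  # n x k, k may be 0
    trait_kind: str = "continuous"
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.env = np.asarray(self.env, dtype=float)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.size == 0:
            self.covariates = np.empty((len(self.samples), 0))
        if self.covariates.shape[0] != len(self.samples):
            self.covariates = self.covariates.T
        if self.trait_kind not in ("continuous", "binary"):
            raise ValueError("trait_kind must be 'continuous' or 'binary'")
        if self.trait_kind == "binary":
            vals = set(np.unique(self.y[~np.isnan(self.y)]))
            if not vals <= {0.0, 1.0}:
                raise ValueError("binary trait must contain only values {0, 1}")

    @property
    def n(self) -> int:
        return len(self.samples)

    def subset(self, idx: np.ndarray) -> "SampleTable":
        return SampleTable(
            samples=[self.samples[i] for i in idx],
            y=self.y[idx],
            env=self.env[idx],
            covariates=self.covariates[idx],
            trait_kind=self.trait_kind,
            covariate_names=list(self.covariate_names),
        )


def _resolve_column(col: np.ndarray, missing: str) -> tuple[np.ndarray, bool]:
    """Orient one dosage column to the minor allele and resolve missingness.

    Returns the resolved column and whether it was flipped.  Under the
    ``mean`` policy NaNs become the observed post-flip dosage mean; under
    ``complete`` they are left for the caller to drop sample-wise.
    """
    col = np.asarray(col, dtype=float).copy()
    mask = np.isnan(col)
    if mask.all():
        raise ValueError("variant has no observed genotypes")
    obs = col[~mask]
    f = obs.sum() / (2.0 * obs.size)
    flipped = f > 0.5
    if flipped:
        col = 2.0 - col  # NaN propagates
    if missing == "mean" and mask.any():
        col[mask] = col[~mask].mean()
    return col, flipped


def load_genotype_table(path: str | Path, snp_set: SnpSet | None = None,
                        missing: str = "mean") -> GenotypeMatrix:
    """Read the plain-TSV genotype dialect (sample ID column + 0/1/2/NA columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    mat = df.apply(pd.to_numeric, errors="coerce")
    if snp_set is not None:
        if snp_set.variant_ids is None:
            raise ValueError("region-style SNP sets require a VCF input")
        missing_ids = [v for v in snp_set.variant_ids if v not in mat.columns]
        if missing_ids:
            raise KeyError(f"variant IDs not present in genotype table: {missing_ids}")
        mat = mat[snp_set.variant_ids]
    return _finalize_matrix(list(mat.index.astype(str)), list(mat.columns.astype(str)),
                            mat.to_numpy(dtype=float), None, None, missing)


def _finalize_matrix(samples, variant_ids, raw, chrom, pos, missing) -> GenotypeMatrix:
    bad = raw[~np.isnan(raw)]
    if bad.size and not np.isin(bad, (0.0, 1.0, 2.0)).all():
        raise ValueError("observed genotype dosages must be 0, 1 or 2")
    cols, flips = [], []
    for j in range(raw.shape[1]):
        try:
            col, fl = _resolve_column(raw[:, j], missing)
        except ValueError as e:
            raise ValueError(f"variant {variant_ids[j]!r}: {e}") from None
        cols.append(col)
        flips.append(fl)
    counts = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    if missing == "complete":
        keep = ~np.isnan(counts).any(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.warning("complete-case policy dropped %d samples with missing genotypes", dropped)
        samples = [s for s, k in zip(samples, keep) if k]
        counts = counts[keep]
    return GenotypeMatrix(samples=samples, variant_ids=variant_ids, counts=counts,
                          chrom=chrom, pos=pos, flipped=np.array(flips, dtype=bool))


def load_genotypes(path: str | Path, snp_set: SnpSet | None = None,
                   missing: str = "mean") -> GenotypeMatrix:
    """Load genotypes for one SNP set from a VCF (``.vcf``/``.vcf.gz``) or TSV table.

    Sites must be diploid and biallelic; multiallelic records raise.  Only
    the GT field is used and phase is ignored.  Dosages are oriented to
    the minor allele and missing genotypes resolved per ``missing``
    ('mean' imputation, the default, or 'complete' case deletion).
    """
    if missing not in ("mean", "complete"):
        raise ValueError("missing policy must be 'mean' or 'complete'")
    path = Path(path)
    if path.suffix == ".tsv" or path.suffixes[-2:] == [".geno", ".tsv"] or path.suffix == ".txt":
        return load_genotype_table(path, snp_set, missing)
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    want: list[str] | None = None
    region = None
    records = []
    if snp_set is not None:
        if snp_set.region is not None:
            region = snp_set.region  # 1-based inclusive; filtered during the scan
        else:
            want = list(snp_set.variant_ids)
    ids, chroms, poss, cols = [], [], [], []
    for rec in vcf:
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        if want is not None and vid not in want:
            continue
        if region is not None and not (rec.CHROM == region[0]
                                       and region[1] <= rec.POS <= region[2]):
            continue
        if len(rec.ALT) != 1:
            raise ValueError(f"variant {vid!r} is not biallelic (ALT={rec.ALT})")
        gt = np.asarray(rec.genotype.array())
        alleles = gt[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        dosage = alleles.sum(axis=1)  # NaN if either allele missing
        ids.append(vid)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        cols.append(dosage)
        records.append(vid)
    if want is not None:
        missing_ids = [v for v in want if v not in records]
        if missing_ids:
            raise KeyError(f"variant IDs not found in {path.name}: {missing_ids}")
        order = [records.index(v) for v in want]
        ids = [ids[i] for i in order]
        chroms = [chroms[i] for i in order]
        poss = [poss[i] for i in order]
        cols = [cols[i] for i in order]
    if not ids:
        raise ValueError(f"no variants loaded from {path}")
    raw = np.column_stack(cols)
    return _finalize_matrix(samples, ids, raw, chroms, np.array(poss), missing)


def write_genotype_table(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write the plain-TSV genotype dialect; round-trips counts exactly."""
    df = pd.DataFrame(geno.counts, index=geno.samples, columns=geno.variant_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.17g")


def load_sample_table(path: str | Path, trait: str, env: str,
                      covariates: list[str] | None = None,
                      trait_kind: str | None = None,
                      center_env: bool = True) -> SampleTable:
    """Read the phenotype TSV; first column is the sample ID.

    ``trait_kind`` is auto-detected (binary iff the trait takes only the
    values 0 and 1) unless given.  A continuous environment is centered
    by default; a {0,1} environment is left as is.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    covariates = covariates or []
    for c in [trait, env, *covariates]:
        if c not in df.columns:
            raise KeyError(f"column {c!r} not found in {Path(path).name} "
                           f"(available: {list(df.columns)})")
    y = df[trait].to_numpy(dtype=float)
    e = df[env].to_numpy(dtype=float)
    if trait_kind is None:
        vals = set(np.unique(y[~np.isnan(y)]))
        trait_kind = "binary" if vals <= {0.0, 1.0} else "continuous"
    env_vals = set(np.unique(e[~np.isnan(e)]))
    if center_env and not env_vals <= {0.0, 1.0}:
        e = e - np.nanmean(e)
    z = df[covariates].to_numpy(dtype=float) if covariates else np.empty((len(df), 0))
    return SampleTable(samples=list(df.index.astype(str)), y=y, env=e, covariates=z,
                       trait_kind=trait_kind, covariate_names=covariates)


def read_snp_sets(path: str | Path) -> list[SnpSet]:
    """Parse the SNP-set file: ``name<TAB>id1,id2,...`` or ``name<TAB>chrom<TAB>start<TAB>end``."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 2:
            ids = [v.strip() for v in parts[1].split(",") if v.strip()]
            if not ids:
                raise ValueError(f"{path}:{lineno}: empty variant list")
            sets.append(SnpSet(name=parts[0], variant_ids=ids))
        elif len(parts) == 4:
            sets.append(SnpSet(name=parts[0], region=(parts[1], int(parts[2]), int(parts[3]))))
        else:
            raise ValueError(f"{path}:{lineno}: expected 2 or 4 tab-separated fields")
    if not sets:
        raise ValueError(f"no SNP sets found in {path}")
    return sets


def align_samples(geno: GenotypeMatrix, pheno: SampleTable) -> tuple[GenotypeMatrix, SampleTable]:
    """Intersect samples (genotype order), dropping phenotype-incomplete ones.

    Samples with a missing trait, environment or covariate value are
    excluded (complete-case analysis); the dropped count is logged.
    Idempotent: aligning aligned inputs changes nothing.
    """
    pheno_pos = {s: i for i, s in enumerate(pheno.samples)}
    gidx, pidx, dropped = [], [], 0
    for i, s in enumerate(geno.samples):
        j = pheno_pos.get(s)
        if j is None:
            continue
        row_ok = (not np.isnan(pheno.y[j]) and not np.isnan(pheno.env[j])
                  and not np.isnan(pheno.covariates[j]).any())
        if not row_ok:
            dropped += 1
            continue
        gidx.append(i)
        pidx.append(j)
    if not gidx:
        raise ValueError("no usable samples shared between genotype and phenotype inputs")
    if dropped:
        logger.warning("align_samples dropped %d samples with missing phenotype data", dropped)
    return geno.subset_samples(np.array(gidx)), pheno.subset(np.array(pidx))
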