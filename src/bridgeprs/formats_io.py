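"""Readers, writers and harmonization for GWAS summary statistics and genotypes.

All containers index variants by genomic identity — ``(chrom, pos, unordered
allele pair)`` — rather than by rsid, because variant names drift across
genome builds and annotation releases while coordinates within a build do not.
Coordinates are 1-based inclusive (PLINK bim convention); dosages count copies
of the declared effect allele and live in ``[0, 2]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("bridgeprs")

VARIANT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele"]

#: complementary base pairs whose strand cannot be resolved from alleles alone
AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class FormatError(ValueError):
    """A file or table does not conform to its declared format."""


def variant_key(chrom, pos, a1, a2) -> tuple:
    """Genomic identity of a variant: chromosome, position, unordered alleles."""
    return (str(chrom), int(pos), frozenset((str(a1), str(a2))))


def _validate_variants(variants: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise FormatError(f"variant table missing columns: {missing}")
    v = variants.copy()
    v["chrom"] = v["chrom"].astype(str)
    v["pos"] = v["pos"].astype(int)
    if (v["pos"] < 1).any():
        raise FormatError("variant positions must be >= 1 (1-based)")
    if (v["effect_allele"] == v["other_allele"]).any():
        raise FormatError("effect and other allele identical for some variant")
    keys = [variant_key(c, p, a, b) for c, p, a, b in
            zip(v["chrom"], v["pos"], v["effect_allele"], v["other_allele"])]
    if len(set(keys)) != len(keys):
        raise FormatError("duplicate (chrom, pos, allele-pair) in variant table")
    return v.reset_index(drop=True)


@dataclass
class SumStats:
    """Per-variant marginal GWAS estimates for one population.

    ``table`` carries the variant identity columns plus ``beta`` (effect in
    trait units per effect-allele count), ``se`` (> 0), ``freq`` (effect-allele
    frequency, strictly inside (0, 1)) and ``pval``; ``n`` is the GWAS sample
    size.
    """

    table: pd.DataFrame
    n: int

    def __post_init__(self):
        needed = VARIANT_COLUMNS + ["beta", "se", "freq", "pval"]
        missing = [c for c in needed if c not in self.table.columns]
        if missing:
            raise FormatError(f"SumStats missing columns: {missing}")
        self.table = _validate_variants(self.table)
        if int(self.n) <= 0:
            raise FormatError("GWAS sample size n must be positive")
        self.n = int(self.n)
        bad = ~((self.table["freq"] > 0) & (self.table["freq"] < 1)
                & (self.table["se"] > 0))
        if bad.any():
            raise FormatError("freq must lie in (0,1) and se must be > 0; "
                              "use read_sumstats to drop offending rows")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def beta(self) -> np.ndarray:
        return self.table["beta"].to_numpy(float)

    @property
    def se(self) -> np.ndarray:
        return self.table["se"].to_numpy(float)

    @property
    def freq(self) -> np.ndarray:
        return self.table["freq"].to_numpy(float)

    @property
    def pval(self) -> np.ndarray:
        return self.table["pval"].to_numpy(float)

    @property
    def keys(self) -> list:
        t = self.table
        return [variant_key(c, p, a, b) for c, p, a, b in
                zip(t["chrom"], t["pos"], t["effect_allele"], t["other_allele"])]

    def subset(self, idx) -> "SumStats":
        return SumStats(self.table.iloc[np.asarray(idx)].reset_index(drop=True),
                        self.n)


@dataclass
class GenotypePanel:
    """Individual-level dosages: ``samples x variants`` effect-allele counts."""

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.variants = _validate_variants(self.variants)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise FormatError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < -1e-9 or \
               np.nanmax(self.dosages, initial=0.0) > 2 + 1e-9:
                raise FormatError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def keys(self) -> list:
        t = self.variants
        return [variant_key(c, p, a, b) for c, p, a, b in
                zip(t["chrom"], t["pos"], t["effect_allele"], t["other_allele"])]

    def subset_variants(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(self.sample_ids,
                             self.variants.iloc[idx].reset_index(drop=True),
                             self.dosages[:, idx])

    def subset_samples(self, sample_ids: Iterable) -> "GenotypePanel":
        wanted = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise KeyError(f"samples absent from panel: {missing[:5]}...")
        idx = [pos[s] for s in wanted]
        return GenotypePanel(np.asarray(wanted, dtype=object),
                             self.variants, self.dosages[idx])


@dataclass
class PhenotypeTable:
    """Trait values and covariates, indexed by unique sample id."""

    sample_ids: np.ndarray
    y: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.y = np.asarray(self.y, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("sample ids must be unique")
        if np.isnan(self.y).any():
            raise FormatError("missing trait values are not allowed")
        if len(self.y) != len(self.sample_ids):
            raise FormatError("y length does not match sample ids")
        if len(self.covariates) not in (0, len(self.sample_ids)):
            raise FormatError("covariate rows do not match sample ids")

    def subset(self, sample_ids: Iterable) -> "PhenotypeTable":
        wanted = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in wanted]
        cov = (self.covariates.iloc[idx].reset_index(drop=True)
               if len(self.covariates) else self.covariates)
        return PhenotypeTable(np.asarray(wanted, dtype=object), self.y[idx], cov)


# ---------------------------------------------------------------------------
# summary-statistic text files
# ---------------------------------------------------------------------------

DEFAULT_COLUMN_MAP = {
    "id": "id", "chrom": "chrom", "pos": "pos",
    "effect_allele": "effect_allele", "other_allele": "other_allele",
    "beta": "beta", "se": "se", "freq": "freq", "n": "n", "pval": "pval",
}


def read_sumstats(path, column_map: Mapping[str, str] | None = None) -> SumStats:
    """Read whitespace/tab-delimited summary statistics with a header row.

    ``column_map`` maps the canonical names (keys of ``DEFAULT_COLUMN_MAP``)
    to the column names used in the file. Rows with a frequency outside (0, 1)
    or a non-positive standard error are dropped with a logged count.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=r"\s+")
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise FormatError(f"summary-statistic file {path} missing required "
                          f"column(s): {missing}")
    df = df.rename(columns={v: k for k, v in cmap.items()})
    n = int(df["n"].iloc[0]) if len(df) else 0
    keep = (df["freq"] > 0) & (df["freq"] < 1) & (df["se"] > 0)
    if (~keep).sum():
        logger.warning("read_sumstats: dropped %d row(s) with freq outside "
                       "(0,1) or se <= 0", int((~keep).sum()))
    df = df.loc[keep].reset_index(drop=True)
    return SumStats(df[VARIANT_COLUMNS + ["beta", "se", "freq", "pval"]], n)


def write_sumstats(s: SumStats, path) -> None:
    out = s.table.copy()
    out["n"] = s.n
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype files: PLINK bed/bim/fam and plain dosage matrices
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit genotype code -> count of the bim A1 allele (01 = missing)
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_BED_CODE = {2: 0b00, 1: 0b10, 0: 0b11}


def _mean_fill(dosages: np.ndarray, on_monomorphic: str) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing calls with the variant mean; flag zero-variance variants."""
    filled = dosages.copy()
    col_mean = np.nanmean(np.where(np.isnan(filled), np.nan, filled), axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(filled))
    filled[nan_r, nan_c] = col_mean[nan_c]
    variance = filled.var(axis=0)
    mono = variance <= 0
    if mono.any():
        if on_monomorphic == "error":
            raise FormatError(f"{int(mono.sum())} monomorphic variant(s) in panel")
        logger.warning("dropping %d monomorphic variant(s)", int(mono.sum()))
    return filled, ~mono


def read_plink(prefix, on_monomorphic: str = "drop") -> GenotypePanel:
    """Read a variant-major PLINK ``.bed/.bim/.fam`` fileset.

    The bim A1 allele is taken as the effect allele, so dosages count A1
    copies. Missing genotypes are mean-filled per variant; monomorphic
    variants are dropped or rejected per ``on_monomorphic``.
    """
    prefix = str(prefix)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"iid": str})
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed lacks the variant-major PLINK magic")
    n, m = len(fam), len(bim)
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_variant * m:
        raise FormatError(f"{prefix}.bed size inconsistent with "
                          f"{n} samples x {m} variants")
    blocks = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, sample order LSB-first within each byte
    codes = np.stack([(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)],
                     axis=2).reshape(m, -1)[:, :n]
    dosages = _BED_CODE_TO_DOSAGE[codes].T  # samples x variants
    variants = pd.DataFrame({
        "id": bim["id"], "chrom": bim["chrom"], "pos": bim["pos"],
        "effect_allele": bim["a1"], "other_allele": bim["a2"]})
    filled, keep = _mean_fill(dosages, on_monomorphic)
    panel = GenotypePanel(fam["iid"].to_numpy(object), variants, filled)
    return panel.subset_variants(np.nonzero(keep)[0]) if not keep.all() else panel


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write hard-call dosages as a variant-major PLINK fileset.

    Dosages are rounded to the nearest integer call; NaN becomes missing.
    """
    prefix = str(prefix)
    n, m = panel.dosages.shape
    v = panel.variants
    bim = pd.DataFrame({"chrom": v["chrom"], "id": v["id"], "cm": 0,
                        "pos": v["pos"], "a1": v["effect_allele"],
                        "a2": v["other_allele"]})
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame({"fid": panel.sample_ids, "iid": panel.sample_ids,
                        "pat": 0, "mat": 0, "sex": 0, "pheno": -9})
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    bytes_per_variant = (n + 3) // 4
    out = np.zeros((m, bytes_per_variant), dtype=np.uint8)
    rounded = np.round(panel.dosages.T)  # variants x samples
    codes = np.full(rounded.shape, 0b01, dtype=np.uint8)
    for dose, code in _DOSAGE_TO_BED_CODE.items():
        codes[rounded == dose] = code
    for shift_i, shift in enumerate((0, 2, 4, 6)):
        cols = np.arange(shift_i, n, 4)
        out[:, (cols // 4)] |= codes[:, cols] << shift
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


def read_dosage_matrix(path, on_monomorphic: str = "drop") -> GenotypePanel:
    """Read a plain text dosage matrix.

    Layout: header row ``id chrom pos effect_allele other_allele s1 s2 ...``,
    one row per variant, dosages possibly fractional, ``NA`` for missing.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"chrom": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"dosage matrix missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in VARIANT_COLUMNS]
    dosages = df[sample_cols].to_numpy(float).T
    filled, keep = _mean_fill(dosages, on_monomorphic)
    panel = GenotypePanel(np.asarray(sample_cols, dtype=object),
                          df[VARIANT_COLUMNS], filled)
    return panel.subset_variants(np.nonzero(keep)[0]) if not keep.all() else panel


def read_genotypes(path, format: str = "plink-bed",
                   on_monomorphic: str = "drop") -> GenotypePanel:
    if format == "plink-bed":
        return read_plink(path, on_monomorphic=on_monomorphic)
    if format == "dosage-matrix":
        return read_dosage_matrix(path, on_monomorphic=on_monomorphic)
    raise ValueError(f"unknown genotype format {format!r}")


def read_phenotypes(path) -> PhenotypeTable:
    """Read ``sample_id  trait  [covariate ...]`` delimited text."""
    df = pd.read_csv(path, sep=r"\s+")
    if not {"sample_id", "trait"} <= set(df.columns):
        raise FormatError("phenotype file needs 'sample_id' and 'trait' columns")
    covars = df.drop(columns=["sample_id", "trait"])
    return PhenotypeTable(df["sample_id"].astype(str).to_numpy(object),
                          df["trait"].to_numpy(float), covars)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    df = pd.DataFrame({"sample_id": pheno.sample_ids, "trait": pheno.y})
    for c in pheno.covariates.columns:
        df[c] = pheno.covariates[c].to_numpy()
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonization and rescaling
# ---------------------------------------------------------------------------

@dataclass
class HarmonizeReport:
    n_a: int
    n_b: int
    n_matched: int
    n_flipped: int
    n_ambiguous_dropped: int


def _is_ambiguous(ea: str, oa: str) -> bool:
    return frozenset((ea, oa)) in AMBIGUOUS_PAIRS


def _flip_inplace(obj, idx: np.ndarray) -> None:
    """Reorient variants at ``idx`` to the opposite effect allele."""
    if isinstance(obj, SumStats):
        t = obj.table
        t.loc[idx, "beta"] = -t.loc[idx, "beta"]
        t.loc[idx, "freq"] = 1.0 - t.loc[idx, "freq"]
        ea = t.loc[idx, "effect_allele"].copy()
        t.loc[idx, "effect_allele"] = t.loc[idx, "other_allele"].to_numpy()
        t.loc[idx, "other_allele"] = ea.to_numpy()
    else:
        obj.dosages[:, idx] = 2.0 - obj.dosages[:, idx]
        v = obj.variants
        ea = v.loc[idx, "effect_allele"].copy()
        v.loc[idx, "effect_allele"] = v.loc[idx, "other_allele"].to_numpy()
        v.loc[idx, "other_allele"] = ea.to_numpy()


def harmonize(a, b, keep_ambiguous: bool = False):
    """Align two variant-bearing datasets on shared genomic identity.

    Variants are matched by (chrom, pos, unordered allele pair). Where ``b``'s
    effect allele is ``a``'s other allele, ``b`` is reoriented (effect sign or
    dosage orientation flipped, frequency complemented). Strand-ambiguous
    A/T and C/G variants are dropped unless ``keep_ambiguous``. Returns
    ``(a_aligned, b_aligned, report)`` with both outputs in ``a``'s order.
    """
    a_keys, b_keys = a.keys, b.keys
    b_pos = {k: i for i, k in enumerate(b_keys)}
    a_idx, b_idx = [], []
    n_amb = 0
    for i, k in enumerate(a_keys):
        j = b_pos.get(k)
        if j is None:
            continue
        ea = a.table["effect_allele"].iloc[i] if isinstance(a, SumStats) \
            else a.variants["effect_allele"].iloc[i]
        oa = a.table["other_allele"].iloc[i] if isinstance(a, SumStats) \
            else a.variants["other_allele"].iloc[i]
        if not keep_ambiguous and _is_ambiguous(ea, oa):
            n_amb += 1
            continue
        a_idx.append(i)
        b_idx.append(j)
    if not a_idx:
        raise FormatError("no overlapping variants after harmonization")

    def _take(obj, idx):
        if isinstance(obj, SumStats):
            return obj.subset(idx)
        return obj.subset_variants(idx)

    a2, b2 = _take(a, a_idx), _take(b, b_idx)
    a_tab = a2.table if isinstance(a2, SumStats) else a2.variants
    b_tab = b2.table if isinstance(b2, SumStats) else b2.variants
    flip = np.nonzero(a_tab["effect_allele"].to_numpy()
                      != b_tab["effect_allele"].to_numpy())[0]
    if len(flip):
        _flip_inplace(b2, flip)
    # matched variants share identity: propagate a's ids so downstream
    # id-based joins see the same name on both sides
    b_tab["id"] = a_tab["id"].to_numpy()
    report = HarmonizeReport(len(a_keys), len(b_keys), len(a_idx), len(flip), n_amb)
    if report.n_matched < len(a_keys):
        logger.info("harmonize: %d/%d variants matched (%d flipped, %d "
                    "ambiguous dropped)", report.n_matched, len(a_keys),
                    report.n_flipped, n_amb)
    return a2, b2, report


def rescale_standardized_sumstats(s: SumStats, target_sd: float) -> SumStats:
    """Map statistics from a unit-variance trait scale to ``target_sd`` units.

    Both the effect size and its standard error scale linearly, so z-scores
    and p-values are untouched.
    """
    if target_sd <= 0:
        raise ValueError("target_sd must be positive")
    t = s.table.copy()
    t["beta"] = t["beta"] * target_sd
    t["se"] = t["se"] * target_sd
    return SumStats(t, s.n)


# ---------------------------------------------------------------------------
# score and weight files
# ---------------------------------------------------------------------------

def write_snp_weights(weights: pd.DataFrame, path) -> None:
    """Write per-variant additive score weights.

    Expects columns id, chrom, pos, effect_allele, weight.
    """
    cols = ["id", "chrom", "pos", "effect_allele", "weight"]
    weights[cols].to_csv(path, sep="\t", index=False)


def read_snp_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = {"id", "chrom", "pos", "effect_allele", "weight"}
    if not needed <= set(df.columns):
        raise FormatError(f"weight file missing columns: {needed - set(df.columns)}")
    return df


def write_scores(sample_ids, prs, path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "PRS": prs}).to_csv(
        path, sep="\t", index=False)


def score_with_weights(panel: GenotypePanel, weights: pd.DataFrame) -> np.ndarray:
    """Apply a SNP-weight file to a panel: PRS = dosages @ weight.

    Variants are matched by (chrom, pos); a weight-file variant whose effect
    allele is the panel's other allele contributes with flipped orientation.
    Variants absent from the panel contribute zero.
    """
    pv = panel.variants
    by_pos = {}
    for j, (c, p, ea, oa) in enumerate(zip(pv["chrom"], pv["pos"],
                                           pv["effect_allele"], pv["other_allele"])):
        by_pos[(str(c), int(p))] = (j, str(ea), str(oa))
    w = np.zeros(panel.dosages.shape[1])
    offset = 0.0
    for _, row in weights.iterrows():
        hit = by_pos.get((str(row["chrom"]), int(row["pos"])))
        if hit is None:
            continue
        j, ea, oa = hit
        if str(row["effect_allele"]) == ea:
            w[j] += row["weight"]
        elif str(row["effect_allele"]) == oa:
            w[j] -= row["weight"]
            offset += 2.0 * row["weight"]
    return panel.dosages @ w + offset
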