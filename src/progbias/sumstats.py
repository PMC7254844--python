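"""GWAS summary statistics: I/O, validation, allele harmonization, LD filtering.

The on-disk dialect is a tab-separated table with header

    SNP CHR BP EA OA EAF BETA SE P INFO

where EA is the effect allele, BETA the per-allele log-odds, and INFO the
imputation quality.  Gzipped files are read and written transparently.  An LD
reference is either a small genotype (dosage) panel from which pairwise r2 is
computed on demand, or an explicit three-column ``SNP_A SNP_B R2`` table.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "INFO"]
REQUIRED = ["SNP", "EA", "OA", "BETA", "SE", "P"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
VALID_ALLELES = frozenset(COMPLEMENT)

# eaf window in which a palindromic (A/T or G/C) variant cannot be oriented
AMBIGUOUS_EAF = (0.4, 0.6)


class SumStatsFormatError(ValueError):
    pass


def is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return oa == ea.map(COMPLEMENT)


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating the record invariants; return (clean, n_dropped).

    Invariants: se > 0, p in (0, 1], distinct valid alleles, eaf in (0, 1)
    and info in [0, 1] where present.
    """
    ok = (
        (df["SE"] > 0)
        & (df["P"] > 0)
        & (df["P"] <= 1)
        & df["EA"].isin(VALID_ALLELES)
        & df["OA"].isin(VALID_ALLELES)
        & (df["EA"] != df["OA"])
        & np.isfinite(df["BETA"])
    )
    if "EAF" in df.columns:
        ok &= df["EAF"].isna() | ((df["EAF"] > 0) & (df["EAF"] < 1))
    if "INFO" in df.columns:
        ok &= df["INFO"].isna() | ((df["INFO"] >= 0) & (df["INFO"] <= 1))
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("validate_sumstats: dropped %d invalid records", n_dropped)
    clean = df.loc[ok].reset_index(drop=True)
    # loose consistency check (warning only): P should roughly match the
    # two-sided normal tail of |beta/se|, up to printed rounding
    if len(clean):
        from scipy import stats as _st

        expected = 2 * _st.norm.sf(np.abs(clean["BETA"] / clean["SE"]))
        with np.errstate(divide="ignore", invalid="ignore"):
            off = (np.maximum(clean["P"], 1e-300) / np.maximum(expected, 1e-300)).to_numpy()
        n_off = int(np.sum((off > 10) | (off < 0.1)))
        if n_off:
            log.warning("%d record(s) have P inconsistent with |beta/se|", n_off)
    return clean, n_dropped


def read_sumstats(path, column_map: dict | None = None, sep: str = "\t") -> pd.DataFrame:
    """Read a summary-statistics table, mapping alternate headers if needed.

    ``column_map`` maps file column names to canonical names (values from
    ``COLUMNS``, plus the special value ``"OR"`` for an odds-ratio column that
    is converted to BETA = log(OR)).  Rows failing record invariants are
    dropped with a logged count.
    """
    df = pd.read_csv(path, sep=sep, compression="infer")
    if column_map:
        df = df.rename(columns=column_map)
    if "OR" in df.columns and "BETA" not in df.columns:
        df["BETA"] = np.log(df["OR"])
        df = df.drop(columns=["OR"])
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise SumStatsFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    for c in ("EAF", "INFO"):
        if c not in df.columns:
            df[c] = np.nan
    for c in ("CHR", "BP"):
        if c not in df.columns:
            df[c] = pd.NA
    df["EA"] = df["EA"].str.upper()
    df["OA"] = df["OA"].str.upper()
    clean, _ = validate_sumstats(df)
    return clean[[c for c in COLUMNS if c in clean.columns]]


def write_sumstats(df: pd.DataFrame, path) -> None:
    cols = [c for c in COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonization


def harmonize(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Align table ``b``'s effects to table ``a``'s effect alleles.

    Variants are intersected on SNP id.  If b reports the same allele pair in
    the opposite orientation, b's beta is negated and its eaf complemented;
    strand flips are resolved by complementing b's alleles first.  Palindromic
    (A/T, G/C) variants whose eaf lies in the ambiguous window are dropped;
    palindromic variants outside it are oriented by frequency agreement.

    Returns the merged table (a's columns plus ``BETA_b, SE_b, P_b, EAF_b,
    INFO_b``) and a report dict of drop/flip counts.
    """
    m = a.merge(b, on="SNP", suffixes=("", "_b"), how="inner")
    report = {
        "n_a": len(a),
        "n_b": len(b),
        "n_common": len(m),
        "n_flipped": 0,
        "n_strand_flipped": 0,
        "n_dropped_palindromic": 0,
        "n_dropped_mismatch": 0,
    }
    if m.empty:
        return m, report

    ea, oa = m["EA"], m["OA"]
    eb, ob = m["EA_b"], m["OA_b"]
    ceb, cob = eb.map(COMPLEMENT), ob.map(COMPLEMENT)
    palin = is_palindromic(ea, oa)

    same = (eb == ea) & (ob == oa)
    swapped = (eb == oa) & (ob == ea)
    strand_same = (ceb == ea) & (cob == oa) & ~palin
    strand_swapped = (ceb == oa) & (cob == ea) & ~palin

    # palindromic variants: allele letters cannot distinguish strand, so use
    # the allele-frequency side; ambiguous frequencies are dropped
    eaf_a = m["EAF"] if "EAF" in m.columns else pd.Series(np.nan, index=m.index)
    eaf_b = m["EAF_b"] if "EAF_b" in m.columns else pd.Series(np.nan, index=m.index)
    lo, hi = AMBIGUOUS_EAF
    ambiguous = palin & (
        eaf_a.isna()
        | eaf_b.isna()
        | ((eaf_a >= lo) & (eaf_a <= hi))
        | ((eaf_b >= lo) & (eaf_b <= hi))
    )
    palin_ok = palin & ~ambiguous
    palin_same = palin_ok & ((eaf_a < 0.5) == (eaf_b < 0.5))
    palin_flip = palin_ok & ~palin_same

    keep_as_is = (same & ~palin) | strand_same | palin_same
    flip = (swapped & ~palin) | strand_swapped | palin_flip
    drop_mismatch = ~(keep_as_is | flip | ambiguous)

    report["n_flipped"] = int((swapped & ~palin).sum() + palin_flip.sum())
    report["n_strand_flipped"] = int((strand_same | strand_swapped).sum())
    report["n_dropped_palindromic"] = int(ambiguous.sum())
    report["n_dropped_mismatch"] = int(drop_mismatch.sum())

    m.loc[flip, "BETA_b"] = -m.loc[flip, "BETA_b"]
    if "EAF_b" in m.columns:
        m.loc[flip, "EAF_b"] = 1 - m.loc[flip, "EAF_b"]
    m = m.loc[keep_as_is | flip].drop(columns=["EA_b", "OA_b"], errors="ignore")
    keep_cols = [c for c in m.columns if not c.endswith("_b")] + [
        c for c in ("BETA_b", "SE_b", "P_b", "EAF_b", "INFO_b") if c in m.columns
    ]
    return m[keep_cols].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# LD reference


@dataclass
class LDReference:
    """Pairwise r2 lookup, from a genotype panel or an explicit pair table.

    Variants absent from the reference are treated as independent (r2 = 0)
    with a single logged warning, so sparse synthetic panels do not silently
    empty a clump/prune run.
    """

    corr2: pd.DataFrame | None = None  # dense r2 matrix, ids x ids
    pairs: dict | None = None  # {(a, b): r2}, symmetric keys
    _warned: set = field(default_factory=set, repr=False)

    @classmethod
    def from_panel(cls, dosages: pd.DataFrame) -> "LDReference":
        """Panel of dosage columns (one per variant); r2 = squared Pearson correlation."""
        x = dosages.loc[:, dosages.std(axis=0) > 0]
        r = np.corrcoef(x.to_numpy(dtype=float), rowvar=False)
        if x.shape[1] == 1:
            r = np.array([[1.0]])
        corr2 = pd.DataFrame(r**2, index=x.columns, columns=x.columns)
        return cls(corr2=corr2)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "LDReference":
        """Three-column SNP_A SNP_B R2 table."""
        pairs = {}
        if table.empty:
            return cls(pairs=pairs)
        for a, b, r2 in table[["SNP_A", "SNP_B", "R2"]].itertuples(index=False):
            if not 0 <= r2 <= 1:
                raise ValueError(f"r2 out of [0,1] for pair ({a},{b}): {r2}")
            pairs[(a, b)] = r2
            pairs[(b, a)] = r2
        return cls(pairs=pairs)

    @classmethod
    def read(cls, path) -> "LDReference":
        df = pd.read_csv(path, sep="\t", compression="infer")
        if {"SNP_A", "SNP_B", "R2"}.issubset(df.columns):
            return cls.from_table(df)
        return cls.from_panel(df)

    def _warn_missing(self, v) -> None:
        if v not in self._warned:
            self._warned.add(v)
            log.warning("variant %s absent from LD reference; assuming r2=0", v)

    def r2(self, a, b) -> float:
        if a == b:
            return 1.0
        if self.corr2 is not None:
            known = self.corr2.index
            if a not in known:
                self._warn_missing(a)
                return 0.0
            if b not in known:
                self._warn_missing(b)
                return 0.0
            return float(self.corr2.at[a, b])
        if (a, b) in self.pairs:
            return self.pairs[(a, b)]
        for v in (a, b):
            if not any(v in k for k in self.pairs):
                self._warn_missing(v)
        return 0.0


# ---------------------------------------------------------------------------
# LD clumping / pruning


def _require_positions(records: pd.DataFrame) -> None:
    if records[["CHR", "BP"]].isna().any().any():
        raise ValueError("records must carry chromosome and position")


def ld_clump(
    records: pd.DataFrame,
    ld: LDReference,
    r2_max: float = 0.2,
    window_bp: int = 250_000,
) -> pd.DataFrame:
    """Greedy P-value-ordered clumping.

    Records are visited in ascending P (ties broken by position); a record is
    retained iff its r2 with every already-retained record on the same
    chromosome within ``window_bp`` (inclusive) is strictly below ``r2_max``.
    """
    if records.empty:
        return records.copy()
    _require_positions(records)
    order = records.sort_values(["P", "BP"], kind="mergesort").index
    kept_rows: list = []
    for i in order:
        row = records.loc[i]
        conflict = False
        for j in kept_rows:
            other = records.loc[j]
            if other["CHR"] == row["CHR"] and abs(int(other["BP"]) - int(row["BP"])) <= window_bp:
                if ld.r2(row["SNP"], other["SNP"]) >= r2_max:
                    conflict = True
                    break
        if not conflict:
            kept_rows.append(i)
    out = records.loc[sorted(kept_rows)].reset_index(drop=True)
    log.info("ld_clump: %d records in, %d retained", len(records), len(out))
    return out


def ld_prune(
    records: pd.DataFrame,
    ld: LDReference,
    window_bp: int = 250_000,
    step_snps: int = 5,
    r2_max: float = 0.1,
) -> pd.DataFrame:
    """Sliding-window LD pruning (P-value agnostic).

    Windows of ``window_bp`` slide along each position-sorted chromosome; in
    every violating pair (r2 >= ``r2_max``) the later-position member is
    dropped, and removal is iterated to its fixed point.  With pairs examined
    in position order the fixed point is canonical and independent of the
    window stride: a variant survives iff no earlier *surviving* variant
    within ``window_bp`` has r2 >= r2_max with it (a dropped variant cannot
    knock out a later one).  ``step_snps`` is accepted for interface
    compatibility with the usual tooling; it does not change the fixed point.
    """
    if records.empty:
        return records.copy()
    _require_positions(records)
    df = records.sort_values(["CHR", "BP"], kind="mergesort")
    keep = {}
    for chrom, sub in df.groupby("CHR", sort=False):
        bps = sub["BP"].astype(int).to_numpy()
        snps = sub["SNP"].to_list()
        idx = list(sub.index)
        kept_pos: list[int] = []
        for k in range(len(idx)):
            ok = True
            for j in reversed(kept_pos):
                if bps[k] - bps[j] > window_bp:
                    break
                if ld.r2(snps[j], snps[k]) >= r2_max:
                    ok = False
                    break
            keep[idx[k]] = ok
            if ok:
                kept_pos.append(k)
    kept_idx = [i for i in records.index if keep.get(i, True)]
    out = records.loc[kept_idx].reset_index(drop=True)
    log.info("ld_prune: %d records in, %d retained", len(records), len(out))
    return out


def filter_records(
    records: pd.DataFrame,
    p_max: float | None = None,
    info_min: float | None = None,
) -> pd.DataFrame:
    """Strict-threshold filtering: keep P < p_max and INFO > info_min."""
    out = records
    if p_max is not None:
        if "P" not in out.columns or out["P"].isna().all():
            raise ValueError("cannot filter on P: field absent")
        out = out[out["P"] < p_max]
    if info_min is not None:
        if "INFO" not in out.columns or out["INFO"].isna().all():
            raise ValueError("cannot filter on INFO: field absent")
        out = out[out["INFO"] > info_min]
    return out.reset_index(drop=True)
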