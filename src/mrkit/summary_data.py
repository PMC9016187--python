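"""GWAS summary statistics: reading, filtering, clumping, harmonization.

The functions here turn two per-trait association tables (exposure and
outcome) into an analysis-ready set of harmonized instruments: variants
expressed on a common effect allele with per-SNP instrument-strength
diagnostics (F statistic, variance explained) attached.

Conventions
-----------
* Effect sizes are on the additive scale (log-odds for binary traits).
* Alleles are single bases in {A, C, G, T}; a variant whose two alleles are
  complementary (A/T or C/G) is *palindromic* and its strand cannot be
  resolved from allele codes alone.
* Genomic coordinates, when present, are 1-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DomainError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical column names of the TSV dialect read and written by this module.
STANDARD_COLUMNS = ("SNP", "effect_allele", "other_allele", "eaf",
                    "beta", "se", "pval", "n", "chrom", "pos")
REQUIRED_COLUMNS = ("SNP", "effect_allele", "other_allele", "beta",
                    "se", "pval", "n")

# Harmonization log actions
KEPT_AS_IS = "kept_as_is"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_INCOMPATIBLE = "dropped_incompatible"
DROPPED_MISSING_IN_OUTCOME = "dropped_missing_in_outcome"


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous allele pairs (A/T or C/G)."""
    return COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele``; ``eaf`` its
    frequency in the GWAS sample (optional).  Validation happens at
    construction so downstream code can rely on the invariants.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise DataError(f"{self.snp_id}: invalid effect allele "
                            f"{self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise DataError(f"{self.snp_id}: invalid other allele "
                            f"{self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.snp_id}: alleles must differ")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise DataError(f"{self.snp_id}: se must be positive and finite")
        if not (0 < self.pval <= 1):
            raise DataError(f"{self.snp_id}: pval must be in (0, 1]")
        if self.n < 1:
            raise DataError(f"{self.snp_id}: sample size must be positive")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise DataError(f"{self.snp_id}: eaf must be in (0, 1)")

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)


@dataclass
class GwasSummaryTable:
    """An ordered, snp_id-unique collection of associations for one trait."""

    trait_label: str
    associations: tuple[VariantAssociation, ...]
    _index: dict[str, VariantAssociation] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.associations = tuple(self.associations)
        self._index = {a.snp_id: a for a in self.associations}
        if len(self._index) != len(self.associations):
            raise DataError(f"{self.trait_label}: duplicate snp_id in table")

    def __len__(self) -> int:
        return len(self.associations)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.associations)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> VariantAssociation | None:
        return self._index.get(snp_id)

    def to_frame(self) -> pd.DataFrame:
        """Render as a DataFrame in the standard column order."""
        return pd.DataFrame(
            {
                "SNP": [a.snp_id for a in self],
                "effect_allele": [a.effect_allele for a in self],
                "other_allele": [a.other_allele for a in self],
                "eaf": [a.eaf for a in self],
                "beta": [a.beta for a in self],
                "se": [a.se for a in self],
                "pval": [a.pval for a in self],
                "n": [a.n for a in self],
                "chrom": [a.chrom for a in self],
                "pos": [a.pos for a in self],
            }
        )

    @classmethod
    def from_frame(cls, trait_label: str, df: pd.DataFrame) -> "GwasSummaryTable":
        assoc = []
        for row in df.itertuples(index=False):
            eaf = getattr(row, "eaf", None)
            chrom = getattr(row, "chrom", None)
            pos = getattr(row, "pos", None)
            assoc.append(VariantAssociation(
                snp_id=str(row.SNP),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=int(row.n),
                eaf=None if eaf is None or pd.isna(eaf) else float(eaf),
                chrom=None if chrom is None or pd.isna(chrom) else str(chrom),
                pos=None if pos is None or pd.isna(pos) else int(pos),
            ))
        return cls(trait_label, tuple(assoc))


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP with exposure and outcome effects on a shared effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    pval_exp: float
    n_exp: int
    beta_out: float
    se_out: float
    pval_out: float
    n_out: int
    eaf_exp: float | None = None
    eaf_out: float | None = None
    r2_exp: float | None = None
    r2_out: float | None = None
    f_stat: float | None = None

    def __post_init__(self) -> None:
        if not self.se_exp > 0:
            raise DataError(f"{self.snp_id}: se_exp must be positive")
        if not self.se_out > 0:
            raise DataError(f"{self.snp_id}: se_out must be positive")


@dataclass
class HarmonizationLog:
    """Per-SNP record of what harmonization did and why."""

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, snp_id: str, action: str, reason: str) -> None:
        self.records.append((snp_id, action, reason))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, action, _ in self.records:
            out[action] = out.get(action, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["SNP", "action", "reason"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def read_summary_table(path, trait_label: str,
                       column_map: Mapping[str, str] | None = None,
                       sep: str = "\t") -> GwasSummaryTable:
    """Read a header-bearing summary-statistics file into a validated table.

    Parameters
    ----------
    path
        Tab-separated file with one header row.
    trait_label
        Name attached to the returned table (e.g. ``"rheumatoid arthritis"``).
    column_map
        Optional mapping from standard names (``SNP``, ``effect_allele``,
        ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``,
        ``chrom``, ``pos``) to the file's column names.

    Rows with unparseable ``beta``/``se``/``pval``, non-positive ``se``,
    invalid alleles or duplicate SNP ids are dropped with a logged count.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    colmap = dict(column_map or {})
    for std in REQUIRED_COLUMNS:
        src = colmap.get(std, std)
        if src not in df.columns:
            raise ConfigurationError(
                f"required column {std!r} (file column {src!r}) "
                f"not found in {path}")
    rename = {colmap.get(std, std): std for std in STANDARD_COLUMNS
              if colmap.get(std, std) in df.columns}
    df = df.rename(columns=rename)

    n_in = len(df)
    for col in ("eaf", "beta", "se", "pval", "n", "pos"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].str.upper().str.strip()
    df["other_allele"] = df["other_allele"].str.upper().str.strip()

    ok = (
        df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
        & df["pval"].notna() & (df["pval"] > 0) & (df["pval"] <= 1)
        & df["n"].notna() & (df["n"] >= 1)
        & df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    if "eaf" in df.columns:
        # out-of-range eaf is treated as missing, not row-fatal
        bad_eaf = df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1))
        df.loc[bad_eaf, "eaf"] = np.nan
    df = df[ok]
    df = df.drop_duplicates(subset="SNP", keep="first")
    n_dropped = n_in - len(df)
    if n_dropped:
        logger.info("%s: dropped %d of %d rows during validation",
                    trait_label, n_dropped, n_in)
    if len(df) == 0:
        raise DataError(f"{trait_label}: no valid rows remain after validation")
    return GwasSummaryTable.from_frame(trait_label, df)


def write_summary_table(table: GwasSummaryTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering and clumping
# ---------------------------------------------------------------------------

def select_significant(table: GwasSummaryTable,
                       p_threshold: float = 5e-8) -> GwasSummaryTable:
    """Keep associations with ``pval`` strictly below the threshold."""
    if not (0 < p_threshold <= 1):
        raise ConfigurationError("p_threshold must be in (0, 1]")
    kept = tuple(a for a in table if a.pval < p_threshold)
    if not kept:
        logger.warning("%s: no SNP passes p < %g", table.trait_label,
                       p_threshold)
    return GwasSummaryTable(table.trait_label, kept)


def _ld_lookup(ld) -> Callable[[str, str], float]:
    """Normalize the accepted LD representations to a symmetric r² lookup."""
    if callable(ld):
        return ld
    if isinstance(ld, pd.DataFrame):
        def from_matrix(a: str, b: str) -> float:
            try:
                return float(ld.loc[a, b])
            except KeyError:
                return 0.0
        return from_matrix
    if isinstance(ld, Mapping):
        def from_mapping(a: str, b: str) -> float:
            v = ld.get((a, b))
            if v is None:
                v = ld.get((b, a), 0.0)
            return float(v)
        return from_mapping
    raise ConfigurationError("ld must be a mapping, DataFrame or callable")


def ld_clump(table: GwasSummaryTable, r2_threshold: float = 0.1,
             ld=None, window_kb: float = 250.0) -> GwasSummaryTable:
    """Greedy LD clumping: keep the most significant SNP of each LD block.

    SNPs are visited in order of ascending p-value (ties broken by snp_id);
    each accepted SNP removes all remaining SNPs with r² >= ``r2_threshold``
    against it.  With ``ld=None`` a distance-only fallback removes SNPs on
    the same chromosome within ``window_kb`` of an accepted SNP, which
    requires coordinates on every variant.  Input order is restored in the
    output, so the result does not depend on row order.
    """
    if not (0 < r2_threshold < 1):
        raise ConfigurationError("r2_threshold must be in (0, 1)")
    if ld is None:
        missing = [a.snp_id for a in table if a.chrom is None or a.pos is None]
        if missing:
            raise ConfigurationError(
                "distance-only clumping requires chrom/pos on every SNP; "
                f"missing for {missing[:5]}")
        def correlated(a: VariantAssociation, b: VariantAssociation) -> bool:
            return (a.chrom == b.chrom
                    and abs(a.pos - b.pos) <= window_kb * 1000)
    else:
        lookup = _ld_lookup(ld)
        def correlated(a: VariantAssociation, b: VariantAssociation) -> bool:
            return lookup(a.snp_id, b.snp_id) >= r2_threshold

    remaining = sorted(table, key=lambda a: (a.pval, a.snp_id))
    kept_ids: set[str] = set()
    while remaining:
        top = remaining.pop(0)
        kept_ids.add(top.snp_id)
        remaining = [a for a in remaining if not correlated(top, a)]
    kept = tuple(a for a in table if a.snp_id in kept_ids)
    return GwasSummaryTable(table.trait_label, kept)


# ---------------------------------------------------------------------------
# Per-SNP instrument diagnostics
# ---------------------------------------------------------------------------

def per_snp_r2(beta: float, se: float, n: int, eaf: float | None = None,
               method: str = "beta_se") -> float:
    """Variance in the trait explained by one SNP.

    ``beta_se`` (default) uses only printed columns:
    r² = β² / (β² + n·se²).  ``eaf`` uses the allele-frequency form
    2·eaf·(1−eaf)·β², appropriate when the trait is standardized.
    """
    if not se > 0:
        raise DomainError("se must be positive")
    if method == "beta_se":
        if n < 2:
            raise DomainError("sample size must be >= 2")
        return beta * beta / (beta * beta + n * se * se)
    if method == "eaf":
        if eaf is None:
            raise DomainError("eaf-based r2 requires an allele frequency")
        return 2.0 * eaf * (1.0 - eaf) * beta * beta
    raise ConfigurationError(f"unknown r2 method {method!r}")


def f_statistic(beta: float, se: float) -> float:
    """Single-instrument F statistic, F = (β/se)²."""
    if not se > 0:
        raise DomainError("se must be positive")
    z = beta / se
    return z * z


def filter_strong(instruments: Sequence[HarmonizedInstrument],
                  f_threshold: float = 10.0,
                  ) -> tuple[list[HarmonizedInstrument], list[HarmonizedInstrument]]:
    """Split instruments into (F >= threshold, weaker) groups."""
    kept, dropped = [], []
    for inst in instruments:
        f = inst.f_stat if inst.f_stat is not None else f_statistic(
            inst.beta_exp, inst.se_exp)
        (kept if f >= f_threshold else dropped).append(inst)
    return kept, dropped


def steiger_filter(instruments: Iterable[HarmonizedInstrument],
                   ) -> tuple[list[HarmonizedInstrument], list[HarmonizedInstrument]]:
    """Directionality filter: keep SNPs explaining more exposure variance.

    A SNP whose variance explained in the outcome exceeds that in the
    exposure is more plausibly acting outcome-first (reverse causation) and
    is removed.  Requires ``r2_exp``/``r2_out`` on every instrument.
    """
    kept, dropped = [], []
    for inst in instruments:
        if inst.r2_exp is None or inst.r2_out is None:
            raise DomainError(f"{inst.snp_id}: r2_exp/r2_out not computed")
        if inst.r2_exp > inst.r2_out:
            kept.append(inst)
        else:
            logger.info("Steiger drop %s: r2_exp=%.3g <= r2_out=%.3g",
                        inst.snp_id, inst.r2_exp, inst.r2_out)
            dropped.append(inst)
    return kept, dropped


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _orient_outcome(exp: VariantAssociation, out: VariantAssociation,
                    window: float) -> tuple[str, float, float | None] | str:
    """Decide how the outcome record maps onto the exposure's allele coding.

    Returns ``(action, beta_out, eaf_out)`` on success, or a drop action
    string.  ``action`` is ``kept_as_is`` or ``flipped``.
    """
    ea_e, oa_e = exp.effect_allele, exp.other_allele
    ea_o, oa_o = out.effect_allele, out.other_allele

    if exp.palindromic:
        if {ea_o, oa_o} != {ea_e, oa_e}:
            return DROPPED_INCOMPATIBLE
        # Nominal letter match; strand flips are indistinguishable, so the
        # allele frequencies must carry the orientation.
        if ea_o == ea_e:
            action, beta, eaf = KEPT_AS_IS, out.beta, out.eaf
        else:
            action, beta, eaf = FLIPPED, -out.beta, _flip_eaf(out.eaf)
        if exp.eaf is None or eaf is None:
            return DROPPED_PALINDROMIC
        if abs(exp.eaf - 0.5) <= window or abs(eaf - 0.5) <= window:
            return DROPPED_PALINDROMIC
        if (exp.eaf - 0.5) * (eaf - 0.5) < 0:
            # frequencies disagree: the outcome is on the other strand
            action = FLIPPED if action == KEPT_AS_IS else KEPT_AS_IS
            beta, eaf = -beta, _flip_eaf(eaf)
        return action, beta, eaf

    if (ea_o, oa_o) == (ea_e, oa_e):
        return KEPT_AS_IS, out.beta, out.eaf
    if (ea_o, oa_o) == (oa_e, ea_e):
        return FLIPPED, -out.beta, _flip_eaf(out.eaf)
    c_ea, c_oa = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
    if (c_ea, c_oa) == (ea_e, oa_e):
        return KEPT_AS_IS, out.beta, out.eaf
    if (c_ea, c_oa) == (oa_e, ea_e):
        return FLIPPED, -out.beta, _flip_eaf(out.eaf)
    return DROPPED_INCOMPATIBLE


def _flip_eaf(eaf: float | None) -> float | None:
    return None if eaf is None else 1.0 - eaf


def harmonize(exposure: GwasSummaryTable, outcome: GwasSummaryTable,
              palindromic_eaf_window: float = 0.08,
              r2_method: str = "beta_se",
              ) -> tuple[list[HarmonizedInstrument], HarmonizationLog]:
    """Express exposure and outcome effects on a common effect allele.

    For each exposure SNP found in the outcome table the outcome record is
    kept as-is, sign/frequency-flipped (when its alleles are swapped or on
    the opposite strand), or dropped (palindromic SNPs with ambiguous or
    missing allele frequencies; irreconcilable allele sets).  Every exposure
    SNP appears exactly once in the returned log.

    Per-SNP variance explained and the F statistic are computed on the way
    out so Steiger and weak-instrument filtering can run directly.
    """
    instruments: list[HarmonizedInstrument] = []
    log = HarmonizationLog()
    for exp in exposure:
        out = outcome.get(exp.snp_id)
        if out is None:
            log.add(exp.snp_id, DROPPED_MISSING_IN_OUTCOME,
                    "SNP absent from outcome table")
            continue
        decision = _orient_outcome(exp, out, palindromic_eaf_window)
        if isinstance(decision, str):
            reason = {
                DROPPED_PALINDROMIC:
                    "palindromic SNP with missing or near-0.5 eaf",
                DROPPED_INCOMPATIBLE:
                    f"allele sets {exp.effect_allele}/{exp.other_allele} vs "
                    f"{out.effect_allele}/{out.other_allele} irreconcilable",
            }[decision]
            log.add(exp.snp_id, decision, reason)
            continue
        action, beta_out, eaf_out = decision
        eaf_for_r2 = exp.eaf
        instruments.append(HarmonizedInstrument(
            snp_id=exp.snp_id,
            effect_allele=exp.effect_allele,
            other_allele=exp.other_allele,
            beta_exp=exp.beta, se_exp=exp.se, pval_exp=exp.pval, n_exp=exp.n,
            beta_out=beta_out, se_out=out.se, pval_out=out.pval, n_out=out.n,
            eaf_exp=exp.eaf, eaf_out=eaf_out,
            r2_exp=per_snp_r2(exp.beta, exp.se, exp.n, eaf_for_r2, r2_method),
            r2_out=per_snp_r2(beta_out, out.se, out.n,
                              eaf_out if eaf_out is not None else exp.eaf,
                              r2_method),
            f_stat=f_statistic(exp.beta, exp.se),
        ))
        log.add(exp.snp_id, action,
                "effect alleles already aligned" if action == KEPT_AS_IS
                else "outcome effect allele recoded to exposure coding")
    return instruments, log


def instruments_to_frame(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Tabular view of a harmonized instrument set."""
    return pd.DataFrame([{
        "SNP": i.snp_id,
        "effect_allele": i.effect_allele,
        "other_allele": i.other_allele,
        "beta_exp": i.beta_exp, "se_exp": i.se_exp,
        "pval_exp": i.pval_exp, "n_exp": i.n_exp,
        "beta_out": i.beta_out, "se_out": i.se_out,
        "pval_out": i.pval_out, "n_out": i.n_out,
        "eaf_exp": i.eaf_exp, "eaf_out": i.eaf_out,
        "r2_exp": i.r2_exp, "r2_out": i.r2_out, "f_stat": i.f_stat,
    } for i in instruments])
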