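import numpy as np
import pandas as pd
import pytest

import mrkit
from mrkit import (ConfigurationError, DataError, DomainError,
                   GwasSummaryTable, VariantAssociation, f_statistic,
                   harmonize, ld_clump, per_snp_r2, read_summary_table,
                   select_significant, steiger_filter)
from mrkit.summary_data import (DROPPED_INCOMPATIBLE, DROPPED_PALINDROMIC,
                                FLIPPED, KEPT_AS_IS)

from conftest import make_instrument, make_variant, table_from


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

STANDARD_TSV = (
    "SNP\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
    "rs1\tA\tG\t0.30\t0.10\t0.01\t1e-20\t50000\n"
    "rs2\tc\tt\t0.20\t-0.05\t0.02\t1e-10\t50000\n"
    "rs3\tG\tA\t0.40\t0.02\t0.01\t0.04\t50000\n"
)


def test_read_summary_table_parses_and_uppercases(tmp_path):
    p = tmp_path / "exp.tsv"
    p.write_text(STANDARD_TSV)
    table = read_summary_table(p, "exposure")
    assert len(table) == 3
    assert table.get("rs2").effect_allele == "C"
    assert table.get("rs1").beta == pytest.approx(0.10)


def test_read_drops_invalid_rows(tmp_path):
    bad = STANDARD_TSV + "rs4\tA\tG\t0.3\t0.1\t0\t1e-5\t50000\n" \
        + "rs5\tA\tG\t0.3\tnot_a_number\t0.01\t1e-5\t50000\n"
    p = tmp_path / "exp.tsv"
    p.write_text(bad)
    table = read_summary_table(p, "exposure")
    assert len(table) == 3 and "rs4" not in table and "rs5" not in table


def test_read_with_column_map_matches_standard_order(tmp_path):
    # same data, shuffled columns and nonstandard names
    remapped = (
        "pvalue\tsize\tvariant\tA1\tA2\tfreq\tb\tstderr\n"
        "1e-20\t50000\trs1\tA\tG\t0.30\t0.10\t0.01\n"
        "1e-10\t50000\trs2\tC\tT\t0.20\t-0.05\t0.02\n"
        "0.04\t50000\trs3\tG\tA\t0.40\t0.02\t0.01\n"
    )
    p1 = tmp_path / "std.tsv"
    p1.write_text(STANDARD_TSV)
    p2 = tmp_path / "mapped.tsv"
    p2.write_text(remapped)
    t1 = read_summary_table(p1, "t")
    t2 = read_summary_table(p2, "t", column_map={
        "SNP": "variant", "effect_allele": "A1", "other_allele": "A2",
        "eaf": "freq", "beta": "b", "se": "stderr", "pval": "pvalue",
        "n": "size"})
    assert t1.associations == t2.associations


def test_read_missing_column_names_the_column(tmp_path):
    p = tmp_path / "exp.tsv"
    p.write_text("SNP\teffect_allele\tbeta\nrs1\tA\t0.1\n")
    with pytest.raises(ConfigurationError, match="other_allele"):
        read_summary_table(p, "exposure")


def test_empty_after_validation_is_data_error(tmp_path):
    p = tmp_path / "exp.tsv"
    p.write_text("SNP\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
                 "rs1\tA\tG\t0.3\t0.1\t0\t1e-5\t50000\n")
    with pytest.raises(DataError):
        read_summary_table(p, "exposure")


def test_duplicate_snp_id_rejected_in_table():
    v = make_variant("rs1")
    with pytest.raises(DataError):
        GwasSummaryTable("t", (v, v))


# ---------------------------------------------------------------------------
# significance filtering
# ---------------------------------------------------------------------------

def test_select_significant_strict_boundary():
    pvals = [1e-9, 4.9e-8, 5e-8, 1e-7]
    t = table_from([make_variant(f"rs{i}", pval=p)
                    for i, p in enumerate(pvals)])
    kept = select_significant(t, 5e-8)
    assert [a.pval for a in kept] == [1e-9, 4.9e-8]
    assert len(select_significant(t, 1.0)) == 4


def test_select_significant_idempotent():
    t = table_from([make_variant(f"rs{i}", pval=p)
                    for i, p in enumerate([1e-10, 1e-6, 0.2])])
    once = select_significant(t, 1e-5)
    twice = select_significant(once, 1e-5)
    assert once.associations == twice.associations


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def _clump_oracle(table, r2_threshold, lookup):
    """Exhaustive greedy reimplementation over the p-sorted list."""
    order = sorted(table, key=lambda a: (a.pval, a.snp_id))
    kept = []
    for cand in order:
        if all(lookup(cand.snp_id, k.snp_id) < r2_threshold for k in kept):
            kept.append(cand)
    return sorted(v.snp_id for v in kept)


def test_ld_clump_independent_snps_all_kept():
    t = table_from([make_variant(f"rs{i}", pval=1e-9) for i in range(3)])
    kept = ld_clump(t, 0.1, ld={})
    assert len(kept) == 3


def test_ld_clump_most_significant_dominates():
    a = make_variant("rsA", pval=1e-10)
    b = make_variant("rsB", pval=1e-9)
    kept = ld_clump(table_from([a, b]), 0.1, ld={("rsA", "rsB"): 0.5})
    assert [v.snp_id for v in kept] == ["rsA"]


def test_ld_clump_matches_greedy_oracle(rng):
    snps = [make_variant(f"rs{i}", pval=float(rng.uniform(1e-12, 1e-6)))
            for i in range(6)]
    ids = [s.snp_id for s in snps]
    mat = {}
    for i in range(6):
        for j in range(i + 1, 6):
            mat[(ids[i], ids[j])] = float(rng.uniform(0, 0.4))

    def lookup(a, b):
        return mat.get((a, b), mat.get((b, a), 0.0))

    kept = ld_clump(table_from(snps), 0.1, ld=mat)
    assert sorted(v.snp_id for v in kept) == _clump_oracle(
        table_from(snps), 0.1, lookup)


def test_ld_clump_row_order_invariant(rng):
    snps = [make_variant(f"rs{i}", pval=float(rng.uniform(1e-12, 1e-6)))
            for i in range(6)]
    mat = {(a.snp_id, b.snp_id): float(rng.uniform(0, 0.3))
           for a in snps for b in snps if a.snp_id < b.snp_id}
    fwd = ld_clump(table_from(snps), 0.1, ld=mat)
    rev = ld_clump(table_from(snps[::-1]), 0.1, ld=mat)
    assert sorted(v.snp_id for v in fwd) == sorted(v.snp_id for v in rev)


def test_ld_clump_distance_mode_requires_coordinates():
    v = make_variant("rs1", chrom=None, pos=None)
    with pytest.raises(ConfigurationError):
        ld_clump(table_from([v]), 0.1, ld=None)


def test_ld_clump_distance_window():
    near = [make_variant("rs1", pval=1e-10, chrom="1", pos=1_000_000),
            make_variant("rs2", pval=1e-9, chrom="1", pos=1_100_000),
            make_variant("rs3", pval=1e-9, chrom="2", pos=1_050_000)]
    kept = ld_clump(table_from(near), 0.1, ld=None, window_kb=250)
    assert sorted(v.snp_id for v in kept) == ["rs1", "rs3"]


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def test_harmonize_swapped_alleles_flip_sign():
    exp = table_from([make_variant("rs1", ea="A", oa="G", beta=0.10)])
    out = table_from([make_variant("rs1", ea="G", oa="A", beta=0.05,
                                   eaf=0.7)])
    instruments, log = harmonize(exp, out)
    assert instruments[0].beta_out == pytest.approx(-0.05)
    assert instruments[0].eaf_out == pytest.approx(0.3)
    assert log.records[0][1] == FLIPPED


def test_harmonize_strand_flip_keeps_sign():
    exp = table_from([make_variant("rs1", ea="A", oa="G", beta=0.10)])
    out = table_from([make_variant("rs1", ea="T", oa="C", beta=0.05)])
    instruments, log = harmonize(exp, out)
    assert instruments[0].beta_out == pytest.approx(0.05)
    assert log.records[0][1] == KEPT_AS_IS


def test_harmonize_palindromic_ambiguous_dropped():
    exp = table_from([make_variant("rs1", ea="A", oa="T", eaf=0.50)])
    out = table_from([make_variant("rs1", ea="A", oa="T", eaf=0.30)])
    instruments, log = harmonize(exp, out)
    assert instruments == []
    assert log.records[0][1] == DROPPED_PALINDROMIC


def test_harmonize_palindromic_resolved_by_eaf():
    exp = table_from([make_variant("rs1", ea="A", oa="T", beta=0.1,
                                   eaf=0.20)])
    # outcome frequency on the other side of 0.5: opposite strand coding
    out = table_from([make_variant("rs1", ea="A", oa="T", beta=0.05,
                                   eaf=0.80)])
    instruments, _ = harmonize(exp, out)
    assert instruments[0].beta_out == pytest.approx(-0.05)
    assert instruments[0].eaf_out == pytest.approx(0.20)


def test_harmonize_incompatible_and_missing_logged_once_each():
    exp = table_from([make_variant("rs1", ea="A", oa="G"),
                      make_variant("rs2", ea="A", oa="G"),
                      make_variant("rs3", ea="A", oa="G")])
    out = table_from([make_variant("rs1", ea="A", oa="C"),
                      make_variant("rs2", ea="G", oa="A")])
    instruments, log = harmonize(exp, out)
    actions = dict((r[0], r[1]) for r in log.records)
    assert actions == {"rs1": DROPPED_INCOMPATIBLE, "rs2": FLIPPED,
                       "rs3": "dropped_missing_in_outcome"}
    assert len(log.records) == len(exp)  # every input SNP exactly once
    assert [i.snp_id for i in instruments] == ["rs2"]


def test_harmonize_idempotent():
    exp = table_from([make_variant("rs1", ea="A", oa="G", beta=0.1),
                      make_variant("rs2", ea="C", oa="T", beta=-0.2,
                                   eaf=0.4)])
    out = table_from([make_variant("rs1", ea="G", oa="A", beta=0.05,
                                   eaf=0.7),
                      make_variant("rs2", ea="C", oa="T", beta=0.02,
                                   eaf=0.4)])
    first, _ = harmonize(exp, out)
    # rebuild an outcome table from the harmonized records and re-harmonize
    out2 = table_from([make_variant(i.snp_id, ea=i.effect_allele,
                                    oa=i.other_allele, beta=i.beta_out,
                                    se=i.se_out, eaf=i.eaf_out)
                       for i in first])
    second, log2 = harmonize(exp, out2)
    assert all(r[1] == KEPT_AS_IS for r in log2.records)
    assert [i.beta_out for i in second] == [i.beta_out for i in first]


# ---------------------------------------------------------------------------
# per-SNP diagnostics
# ---------------------------------------------------------------------------

def test_per_snp_r2_formula():
    assert per_snp_r2(0.0, 0.01, 1000) == 0.0
    assert per_snp_r2(0.1, 0.01, 10_000) == pytest.approx(0.01 / 1.01)
    # monotone in |beta| at fixed se, n
    vals = [per_snp_r2(b, 0.01, 1000) for b in (0.01, 0.05, 0.1, 0.5)]
    assert vals == sorted(vals)
    with pytest.raises(DomainError):
        per_snp_r2(0.1, 0.01, 1)


def test_per_snp_r2_eaf_variant():
    assert per_snp_r2(0.1, 0.01, 1000, eaf=0.25, method="eaf") == \
        pytest.approx(2 * 0.25 * 0.75 * 0.01)
    with pytest.raises(DomainError):
        per_snp_r2(0.1, 0.01, 1000, method="eaf")


def test_f_statistic_boundary():
    assert f_statistic(0.1, 0.01) == pytest.approx(100.0)
    assert f_statistic(0.03, 0.01) == pytest.approx(9.0)
    kept, dropped = mrkit.filter_strong(
        [make_instrument("a", beta_exp=0.1, se_exp=0.01),
         make_instrument("b", beta_exp=0.03, se_exp=0.01)], 10.0)
    assert [i.snp_id for i in kept] == ["a"]
    assert [i.snp_id for i in dropped] == ["b"]


def test_steiger_filter_directionality():
    fwd = make_instrument("fwd", beta_exp=0.3, beta_out=0.01)
    rev = make_instrument("rev", beta_exp=0.01, beta_out=0.3)
    kept, dropped = steiger_filter([fwd, rev])
    assert [i.snp_id for i in kept] == ["fwd"]
    assert [i.snp_id for i in dropped] == ["rev"]


def test_steiger_catches_planted_reverse_snp():
    from mrkit import SyntheticScenario, generate
    sc = SyntheticScenario(n_snp=10, beta_causal=0.1, frac_reverse=0.1,
                           n_exp=2_000_000, n_out=2_000_000, seed=11)
    exposure, outcome, truth = generate(sc)
    instruments, _ = harmonize(exposure, outcome)
    kept, dropped = steiger_filter(instruments)
    planted = {truth.snp_ids[i] for i in np.nonzero(truth.is_reverse)[0]}
    assert {i.snp_id for i in dropped} == planted
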