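"""IO, instrument selection, clumping and harmonization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrmediate import (
    InstrumentSelectionConfig,
    LDMatrix,
    VariantAssociation,
    clump_greedy,
    f_statistic,
    harmonize,
    read_sumstats,
    select_instruments,
    write_sumstats,
)
from conftest import make_variant


# ---------------------------------------------------------------------------
# IO


def _three_records():
    return [
        make_variant("rs1", "A", "G", beta=0.12, se=0.01, pval=2.5e-9, eaf=0.31),
        make_variant("rs2", "T", "C", beta=-0.08, se=0.012, pval=3e-7, eaf=0.12,
                     chrom="2", pos=500),
        VariantAssociation("rs3", "G", "C", beta=0.05, se=0.02, pval=0.01),
    ]


def test_write_read_round_trip(tmp_path):
    """Canonical TSV round-trips bit-identically, optional fields included."""
    records = _three_records()
    path = tmp_path / "sumstats.tsv"
    write_sumstats(records, path)
    back = read_sumstats(path)
    assert back == records
    # a second round trip is byte-identical
    path2 = tmp_path / "again.tsv"
    write_sumstats(back, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_column_map_aliases(tmp_path):
    """Aliased headers parse to the same records as the canonical header."""
    canonical = tmp_path / "canon.tsv"
    write_sumstats(_three_records(), canonical)
    aliased = tmp_path / "alias.tsv"
    text = canonical.read_text()
    header, rest = text.split("\n", 1)
    header = header.replace("SNP", "rsid").replace("effect_allele", "EA").replace(
        "other_allele", "NEA"
    )
    aliased.write_text(header + "\n" + rest)
    remapped = read_sumstats(
        aliased, column_map={"rsid": "SNP", "EA": "effect_allele", "NEA": "other_allele"}
    )
    assert remapped == read_sumstats(canonical)


def test_invalid_row_strict_vs_lenient(tmp_path):
    path = tmp_path / "bad.tsv"
    write_sumstats(_three_records(), path)
    lines = path.read_text().splitlines()
    lines.append("rs4\t\t\tA\tG\t0.2\t0.1\t0\t0.5\t")  # se = 0
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValueError, match="rs4"):
        read_sumstats(path, strict=True)
    with pytest.warns(UserWarning, match="skipping"):
        records = read_sumstats(path, strict=False)
    assert [r.snp_id for r in records] == ["rs1", "rs2", "rs3"]


def test_missing_mandatory_column_is_fatal(tmp_path):
    path = tmp_path / "nocol.tsv"
    path.write_text("SNP\teffect_allele\tbeta\tse\tpval\nrs1\tA\t0.1\t0.01\t1e-8\n")
    with pytest.raises(ValueError, match="other_allele"):
        read_sumstats(path)


# ---------------------------------------------------------------------------
# instrument strength and selection


@pytest.mark.parametrize(
    "beta,se,expected",
    [(0.1, 0.05, 4.0), (0.1, 0.01, 100.0), (-0.2, 0.02, 100.0)],
)
def test_f_statistic(beta, se, expected):
    assert f_statistic(beta, se) == pytest.approx(expected)


def test_f_statistic_rejects_nonpositive_se():
    with pytest.raises(ValueError):
        f_statistic(0.1, 0.0)


def test_select_instruments_filters():
    cfg = InstrumentSelectionConfig()
    records = [
        make_variant("keep", beta=0.1, se=0.01, pval=1e-8),
        make_variant("border_p", pval=2e-5),                     # above 1e-5
        make_variant("rare", pval=1e-8, eaf=0.005),              # MAF < 0.01
        make_variant("weak", beta=0.1, se=0.05, pval=1e-8),      # F = 4
        make_variant("f_boundary", beta=0.1, se=0.1 / np.sqrt(10), pval=1e-8),
    ]
    sel = select_instruments(records, cfg)
    assert {r.snp_id for r in sel} == {"keep", "f_boundary"}  # F == 10 retained
    # the relaxed threshold for SNP-poor exposures rescues the borderline SNP
    sel_sparse = select_instruments(records, cfg, sparse=True)
    assert "border_p" in {r.snp_id for r in sel_sparse}


def test_select_missing_eaf_passes_with_warning():
    rec = make_variant("noeaf", eaf=None)
    sel = select_instruments([rec])
    assert sel.instruments == [rec]
    assert any("eaf" in w for w in sel.warnings)


def test_select_empty_result_is_status_not_exception():
    sel = select_instruments([make_variant("weakp", pval=0.5)])
    assert sel.instruments == [] and sel.status == "no-instruments"


@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=30))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_select_monotone_in_pval_threshold(pvals):
    """Relaxing the p-value threshold never removes a selected SNP."""
    records = [
        make_variant(f"rs{i}", beta=0.1, se=0.01, pval=p) for i, p in enumerate(pvals)
    ]
    tight = select_instruments(records, InstrumentSelectionConfig(pval_threshold=1e-5))
    loose = select_instruments(records, InstrumentSelectionConfig(pval_threshold=1e-3))
    assert {r.snp_id for r in tight} <= {r.snp_id for r in loose}


# ---------------------------------------------------------------------------
# clumping


def _clump_oracle(records, r2, threshold, window_kb):
    """Independent step-by-step enumeration of the greedy definition."""
    remaining = {r.snp_id: r for r in records}
    kept = []
    while remaining:
        index = min(remaining.values(), key=lambda r: (r.pval, r.snp_id))
        kept.append(index)
        del remaining[index.snp_id]
        for other in list(remaining.values()):
            same_chrom = (
                index.chrom is None or other.chrom is None or index.chrom == other.chrom
            )
            near = (
                index.pos is None
                or other.pos is None
                or abs(index.pos - other.pos) <= window_kb * 1000
            )
            key = frozenset((index.snp_id, other.snp_id))
            if same_chrom and near and r2.get(key, 0.0) >= threshold:
                del remaining[other.snp_id]
    return sorted(kept, key=lambda r: (r.chrom or "", r.pos or -1, r.snp_id))


def test_clump_no_ld_keeps_everything():
    records = [make_variant(f"rs{i}", pos=i * 10_000) for i in range(4)]
    assert len(clump_greedy(records, LDMatrix(), 0.001, 10_000)) == 4


def test_clump_pair_keeps_smaller_pval():
    a = make_variant("lead", pval=1e-8, pos=1_000_000)
    b = make_variant("shadow", pval=1e-6, pos=1_001_000)
    ld = LDMatrix({("lead", "shadow"): 1.0})
    kept = clump_greedy([b, a], ld, 0.001, 10_000)
    assert [r.snp_id for r in kept] == ["lead"]


def test_clump_matches_enumeration_oracle_and_is_order_invariant():
    rng = np.random.default_rng(7)
    records = [
        make_variant(f"rs{i}", pval=float(rng.uniform(1e-10, 1e-5)),
                     pos=int(1e6 + i * 2000))
        for i in range(5)
    ]
    r2 = {}
    ld = LDMatrix()
    for i in range(5):
        for k in range(i + 1, 5):
            val = float(rng.uniform(0, 1))
            r2[frozenset((f"rs{i}", f"rs{k}"))] = val
            ld.set(f"rs{i}", f"rs{k}", val)
    expected = [r.snp_id for r in _clump_oracle(records, r2, 0.3, 10_000)]
    got = [r.snp_id for r in clump_greedy(records, ld, 0.3, 10_000)]
    assert got == expected
    shuffled = list(records[::-1])
    assert [r.snp_id for r in clump_greedy(shuffled, ld, 0.3, 10_000)] == expected
    # every dropped SNP is within-window r2 >= threshold of some kept SNP
    dropped = {r.snp_id for r in records} - set(got)
    for d in dropped:
        assert any(r2.get(frozenset((d, k)), 0.0) >= 0.3 for k in got)


# ---------------------------------------------------------------------------
# harmonization


def _pair(exp_alleles, out_alleles, out_beta=0.05, exp_eaf=0.3, out_eaf=0.3):
    exp = make_variant("rs1", *exp_alleles, beta=0.1, eaf=exp_eaf)
    out = make_variant("rs1", *out_alleles, beta=out_beta, se=0.02, eaf=out_eaf)
    return [exp], [out]


def test_harmonize_identity():
    hset = harmonize(*_pair(("A", "G"), ("A", "G")))
    assert hset.beta_out[0] == 0.05
    assert hset.audit == [("rs1", "kept-as-is", "")]


def test_harmonize_allele_swap_negates_outcome():
    hset = harmonize(*_pair(("A", "G"), ("G", "A")))
    assert hset.beta_out[0] == -0.05
    assert hset.audit[0][1] == "outcome-flipped"


def test_harmonize_strand_flip():
    # exposure A/G, outcome reported on the other strand as T/C
    hset = harmonize(*_pair(("A", "G"), ("T", "C")))
    assert hset.beta_out[0] == 0.05
    assert hset.audit[0][1] == "strand-flipped"
    # other strand AND swapped order: complement then negate
    hset = harmonize(*_pair(("A", "G"), ("C", "T")))
    assert hset.beta_out[0] == -0.05


def test_harmonize_palindromic():
    # ambiguous frequency: dropped
    hset = harmonize(*_pair(("A", "T"), ("A", "T"), exp_eaf=0.50, out_eaf=0.50))
    assert len(hset) == 0
    assert hset.audit == [("rs1", "dropped", "palindromic-ambiguous")]
    # frequencies agree outside the window: kept as-is
    hset = harmonize(*_pair(("A", "T"), ("A", "T"), exp_eaf=0.2, out_eaf=0.25))
    assert hset.beta_out[0] == 0.05
    # frequencies disagree: strand flip inferred
    hset = harmonize(*_pair(("A", "T"), ("A", "T"), exp_eaf=0.2, out_eaf=0.8))
    assert hset.beta_out[0] == -0.05
    assert hset.audit[0][1] == "strand-flipped"


def test_harmonize_incompatible_dropped():
    hset = harmonize(*_pair(("A", "G"), ("A", "C")))
    assert len(hset) == 0
    assert hset.audit[0][2] == "incompatible-alleles"


def test_harmonize_empty_intersection():
    exp = [make_variant("rs1")]
    out = [make_variant("rs2")]
    assert len(harmonize(exp, out)) == 0


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_harmonize_double_swap_is_identity(seed):
    """Flipping outcome alleles twice restores the original betas exactly."""
    rng = np.random.default_rng(seed)
    exp = [make_variant("rs1", "A", "G", beta=float(rng.normal()), eaf=0.3)]
    beta = float(rng.normal())
    out = [make_variant("rs1", "A", "G", beta=beta, eaf=0.3)]
    swapped = [make_variant("rs1", "G", "A", beta=-beta, eaf=0.7)]
    direct = harmonize(exp, out)
    via_swap = harmonize(exp, swapped)
    assert direct.beta_out[0] == via_swap.beta_out[0] == beta


def test_harmonize_idempotent():
    """Harmonizing an already-harmonized pair changes nothing."""
    rng = np.random.default_rng(3)
    exp, out = [], []
    alleles = [("A", "G"), ("T", "C"), ("G", "A"), ("A", "T")]
    for i, (ea, oa) in enumerate(alleles):
        exp.append(make_variant(f"rs{i}", ea, oa, beta=float(rng.normal()), eaf=0.2))
        out.append(make_variant(f"rs{i}", oa, ea, beta=float(rng.normal()), eaf=0.8))
    first = harmonize(exp, out)
    aligned = [
        make_variant(
            s, exp[i].effect_allele, exp[i].other_allele,
            beta=float(first.beta_out[k]), se=float(first.se_out[k]), eaf=0.2,
        )
        for k, s in enumerate(first.snp_ids)
        for i in [int(s[2:])]
    ]
    second = harmonize([e for e in exp if e.snp_id in first.snp_ids], aligned)
    assert second.snp_ids == first.snp_ids
    np.testing.assert_array_equal(second.beta_out, first.beta_out)
    assert all(tag == "kept-as-is" for _, tag, _ in second.audit)
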