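"""Unit and property tests for the cohort simulator and strand accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methleak.errors import ConfigurationError
from methleak.synthetic_cohort import (
    BASES,
    CohortDesign,
    apply_disruption_accounting,
    emit_array_like_betas,
    expected_pooled_rate,
    reverse_base_probs,
    simulate_cohort,
    simulate_reverse_base_evidence,
)


class TestDisruptionAccounting:
    @pytest.mark.parametrize(
        "genotype, m, cph, expected",
        [
            # wild type: both strands concordant at m
            ("CC", 1.0, 0.0, (1.0, 1.0, 1.0)),
            ("CC", 0.3, 0.0, (0.3, 0.3, 1.0)),
            # C/A het: alt forward reads dropped, alt reverse reads ~unmethylated
            ("AC", 1.0, 0.0, (1.0, 0.5, 0.5)),
            ("CG", 1.0, 0.0, (1.0, 0.5, 0.5)),
            # C/T het: alt forward reads miscounted unmethylated; strands concordant
            ("CT", 1.0, 0.01, (0.5, 0.505, 1.0)),
            # homozygous alt
            ("TT", 1.0, 0.01, (0.0, 0.01, 1.0)),
        ],
    )
    def test_error_free_rates(self, genotype, m, cph, expected):
        fwd, rev, cf = apply_disruption_accounting(genotype, m, cph_methylation_rate=cph)
        assert fwd == pytest.approx(expected[0], abs=1e-12)
        assert rev == pytest.approx(expected[1], abs=1e-12)
        assert cf == expected[2]

    def test_hom_alt_unmeasurable_forward(self):
        """A/A and G/G dyads produce no forward-strand cytosine reads."""
        for gt in ("AA", "GG", "AG"):
            fwd, rev, cf = apply_disruption_accounting(gt, 0.8, cph_methylation_rate=0.01)
            if "T" not in gt and "C" not in gt:
                assert cf == 0.0 and np.isnan(fwd)
            assert rev == pytest.approx(0.01)

    def test_het_forward_excess_is_half_at_full_methylation(self):
        """The heterozygote signature: ~50 points more forward methylation."""
        fwd, rev, _ = apply_disruption_accounting("AC", 1.0)
        assert fwd - rev == pytest.approx(0.5)

    def test_per_read_enumeration_oracle(self):
        """Independent per-allele, per-read enumeration of the expected rates."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            g = "".join(rng.choice(list(BASES), size=2))
            m = float(rng.random())
            nc, e, cph = 0.004, 0.002, 0.015
            fwd, rev, cf = apply_disruption_accounting(
                g, m, non_conversion_rate=nc, sequencing_error_rate=e, cph_methylation_rate=cph
            )

            def scored_meth(raw):
                q = raw * (1 - nc) + (1 - raw) * nc
                return q * (1 - e / 3) + (1 - q) * (e / 3)

            fwd_alleles = [a for a in g if a in "CT"]
            assert cf == len(fwd_alleles) / 2
            if fwd_alleles:
                exp_fwd = np.mean([scored_meth(m if a == "C" else 0.0) for a in fwd_alleles])
                assert fwd == pytest.approx(exp_fwd, abs=1e-12)
            else:
                assert np.isnan(fwd)
            exp_rev = np.mean([scored_meth(m if a == "C" else cph) for a in g])
            assert rev == pytest.approx(exp_rev, abs=1e-12)

    @given(
        m=st.floats(0.0, 1.0),
        nc=st.floats(0.0, 0.05),
        e=st.floats(0.0, 0.01),
        cph=st.floats(0.0, 0.05),
        g=st.tuples(st.sampled_from(BASES), st.sampled_from(BASES)),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_rates_stay_probabilities(self, m, nc, e, cph, g):
        fwd, rev, cf = apply_disruption_accounting(
            g, m, non_conversion_rate=nc, sequencing_error_rate=e, cph_methylation_rate=cph
        )
        assert cf in (0.0, 0.5, 1.0)
        assert 0.0 <= rev <= 1.0
        if not np.isnan(fwd):
            assert 0.0 <= fwd <= 1.0


class TestReverseBaseEvidence:
    def test_homozygous_reference_gives_pure_g(self):
        counts = simulate_reverse_base_evidence("CC", 20, 0.0, rng=0)
        assert counts == {"A": 0, "C": 0, "G": 20, "T": 0}

    @pytest.mark.parametrize("genotype, expected_bases", [("AC", {"G", "T"}), ("CT", {"G", "A"})])
    def test_het_expected_split(self, genotype, expected_bases):
        """Expected counts follow the allele-sampling distribution (10/10)."""
        p = reverse_base_probs(genotype, 0.0)
        expected = {b: 20 * p[BASES.index(b)] for b in BASES}
        assert {b for b, v in expected.items() if v > 0} == expected_bases
        assert all(v == pytest.approx(10.0) for b, v in expected.items() if b in expected_bases)
        # and empirical means converge there
        rng = np.random.default_rng(5)
        totals = np.zeros(4)
        n_rep = 400
        for _ in range(n_rep):
            c = simulate_reverse_base_evidence(genotype, 20, 0.0, rng=rng)
            totals += [c[b] for b in BASES]
        means = totals / n_rep
        np.testing.assert_allclose(means, [expected[b] for b in BASES], atol=0.6)

    def test_counts_sum_to_coverage(self):
        c = simulate_reverse_base_evidence("AG", 33, 0.01, rng=3)
        assert sum(c.values()) == 33


class TestCohortSimulation:
    def test_seed_reproducibility(self, small_design, small_cohort):
        other = simulate_cohort(small_design)
        pd.testing.assert_frame_equal(other.samples, small_cohort.samples)
        pd.testing.assert_frame_equal(other.truth.snps, small_cohort.truth.snps)
        for sid in small_cohort.evidence:
            pd.testing.assert_frame_equal(other.evidence[sid], small_cohort.evidence[sid])

    def test_counts_conserve_coverage(self, small_cohort):
        for sid, ev in small_cohort.evidence.items():
            rev_cov = ev["rev_meth"] + ev["rev_unmeth"]
            bases = ev[["rev_A", "rev_C", "rev_G", "rev_T"]].sum(axis=1)
            assert (bases == rev_cov).all()
            assert (ev["fwd_meth"] >= 0).all() and (ev["fwd_unmeth"] >= 0).all()

    def test_truth_invariants(self, small_cohort):
        truth = small_cohort.truth
        assert truth.dosages.isin([0, 1, 2]).all().all()
        # disrupting SNPs sit exactly at the forward C; meQTL SNPs within 10 kb
        snp_pos = truth.snps.set_index("snp_id")["pos"]
        disrupted = truth.cpgs[truth.cpgs["disrupt_snp"].notna()]
        for _, row in disrupted.iterrows():
            p = snp_pos[row["disrupt_snp"]]
            assert row["pos"] <= p < row["pos"] + 2
        linked = truth.cpgs[truth.cpgs["linked_snp"].notna()]
        assert len(linked) > 0
        for _, row in linked.iterrows():
            assert abs(snp_pos[row["linked_snp"]] - row["pos"]) <= 10_000

    def test_mz_twins_share_genotypes_dz_share_partially(self):
        design = CohortDesign(
            n_individuals=8,
            tissues=("t",),
            relationships=((0, 1, "MZ"), (2, 3, "MZ"), (4, 5, "DZ"), (6, 7, "DZ")),
            n_cpgs=200,
            n_snps=200,
            fraction_cpg_disrupting=0.0,
            fraction_indirect_meqtl=0.0,
            maf_beta_params=(2.0, 2.0),
            seed=13,
        )
        res = simulate_cohort(design)
        d = res.truth.dosages
        assert (d["ind000"] == d["ind001"]).all()
        assert (d["ind002"] == d["ind003"]).all()
        # DZ pairs: correlated but not identical
        for a, b in (("ind004", "ind005"), ("ind006", "ind007")):
            assert (d[a] == d[b]).mean() < 1.0
            assert np.corrcoef(d[a], d[b])[0, 1] > 0.2

    def test_full_methylation_measured_rate_matches_binomial_expectation(self):
        """Hom-ref fully methylated CpG at 30x with 0.5 % non-conversion reads ~0.995."""
        rng = np.random.default_rng(21)
        fwd, rev, _ = apply_disruption_accounting("CC", 1.0, non_conversion_rate=0.005)
        n, cov = 400, 30
        meth = rng.binomial(cov, fwd, size=n)
        mean_rate = (meth / cov).mean()
        se = np.sqrt(fwd * (1 - fwd) / cov / n)
        assert abs(mean_rate - 0.995) <= 2 * se + 1e-9

    def test_high_coverage_rates_converge_to_accounting(self):
        """At 10,000x with zero errors, measured rates match the model within 0.5 %."""
        design = CohortDesign(
            n_individuals=4,
            tissues=("t",),
            n_cpgs=60,
            n_snps=40,
            fraction_cpg_disrupting=0.5,
            fraction_indirect_meqtl=0.0,
            coverage_mean_per_strand=10_000.0,
            non_conversion_rate=0.0,
            sequencing_error_rate=0.0,
            cph_methylation_rate=0.01,
            residual_sd=0.0,
            tissue_effect_sd=0.0,
            seed=3,
        )
        res = simulate_cohort(design)
        truth = res.truth
        snp_alt = truth.snps.set_index("snp_id")["alt"]
        for sid, ev in res.evidence.items():
            ind = res.samples.set_index("sample_id").loc[sid, "individual_id"]
            for i, row in truth.cpgs.iterrows():
                m = truth.true_meth.loc[row["cpg_id"], sid]
                if pd.isna(row["disrupt_snp"]):
                    gt = "CC"
                else:
                    d = truth.dosages.loc[row["disrupt_snp"], ind]
                    alt = snp_alt[row["disrupt_snp"]]
                    gt = "CC" if d == 0 else ("C" + alt if d == 1 else alt + alt)
                exp_fwd, exp_rev, cf = apply_disruption_accounting(gt, m, cph_methylation_rate=0.01)
                erow = ev.iloc[i]
                rev_cov = erow["rev_meth"] + erow["rev_unmeth"]
                # binomial sampling noise at this coverage: allow max(0.5 %, 4.5 SE)
                tol = max(0.005, 4.5 * np.sqrt(exp_rev * (1 - exp_rev) / rev_cov))
                assert erow["rev_meth"] / rev_cov == pytest.approx(exp_rev, abs=tol)
                fwd_cov = erow["fwd_meth"] + erow["fwd_unmeth"]
                if cf == 0.0:
                    assert fwd_cov == 0
                else:
                    tol = max(0.005, 4.5 * np.sqrt(exp_fwd * (1 - exp_fwd) / fwd_cov))
                    assert erow["fwd_meth"] / fwd_cov == pytest.approx(exp_fwd, abs=tol)

    def test_null_cohort_has_no_dosage_correlation_beyond_chance(self):
        """Without disrupting SNPs or meQTLs, |r| > 0.5 occurs only at the
        chance rate expected for the cohort size (permutation-estimated)."""
        design = CohortDesign(
            n_individuals=8,
            tissues=("t1", "t2"),
            n_cpgs=1000,
            n_snps=50,
            fraction_cpg_disrupting=0.0,
            fraction_indirect_meqtl=0.0,
            meqtl_effect=0.0,
            maf_beta_params=(2.0, 2.0),
            seed=17,
        )
        res = simulate_cohort(design)
        inds = list(res.truth.dosages.columns)
        meth = res.truth.true_meth
        per_ind = meth.T.groupby([s.rsplit("_", 1)[0] for s in meth.columns]).mean().T[inds]
        rng = np.random.default_rng(1)
        snp = res.truth.dosages.iloc[0].to_numpy(dtype=float)
        if np.ptp(snp) == 0:  # pragma: no cover - guard for a monomorphic draw
            snp = res.truth.dosages.iloc[1].to_numpy(dtype=float)

        def frac_high(dosage_vec):
            vals = per_ind.to_numpy()
            keep = vals.std(axis=1) > 0
            r = np.corrcoef(vals[keep], dosage_vec)[:-1, -1]
            return np.mean(np.abs(r) > 0.5)

        observed = frac_high(snp)
        permuted = np.mean([frac_high(rng.permutation(snp)) for _ in range(20)])
        assert abs(observed - permuted) < 0.05

    def test_invalid_design_names_field(self):
        with pytest.raises(ConfigurationError, match="fraction_cpg_disrupting"):
            CohortDesign(fraction_cpg_disrupting=1.5).validate()
        with pytest.raises(ConfigurationError, match="n_individuals"):
            CohortDesign(n_individuals=0).validate()
        with pytest.raises(ConfigurationError, match="disruption_allele_probs"):
            CohortDesign(disruption_allele_probs=(0.5, 0.5, 0.5)).validate()


class TestArrayLikeBetas:
    def _twin_design(self, noise_seed=0):
        return CohortDesign(
            n_individuals=8,
            tissues=("adipose",),
            relationships=((0, 1, "MZ"), (2, 3, "MZ"), (4, 5, "DZ"), (6, 7, "DZ")),
            n_cpgs=200,
            n_snps=100,
            fraction_cpg_disrupting=0.5,
            fraction_indirect_meqtl=0.0,
            maf_beta_params=(2.0, 2.0),
            residual_sd=0.0,
            tissue_effect_sd=0.0,
            seed=29,
        )

    def test_mz_twins_near_perfect_correlation_as_noise_vanishes(self):
        res = simulate_cohort(self._twin_design())
        sel = res.truth.disrupted_cpg_ids()
        betas = emit_array_like_betas(res.truth, cpg_ids=sel, noise_sd=0.0, rng=0)
        a, b = "ind000_adipose", "ind001_adipose"
        r = np.corrcoef(betas[a], betas[b])[0, 1]
        assert r > 0.999

    def test_linear_dosage_construction(self):
        """With a purely genetic linear effect and no noise, betas are exactly
        b0 + d*delta across dosage groups."""
        design = CohortDesign(
            n_individuals=6,
            tissues=("t",),
            n_cpgs=50,
            n_snps=30,
            fraction_cpg_disrupting=0.0,
            fraction_indirect_meqtl=0.2,
            meqtl_effect=0.3,
            residual_sd=0.0,
            tissue_effect_sd=0.0,
            baseline_mixture=(1.0, (8.0, 8.0), (0.5, 10.0)),
            seed=4,
        )
        res = simulate_cohort(design)
        truth = res.truth
        betas = emit_array_like_betas(truth, noise_sd=0.0, rng=0)
        linked = truth.cpgs[truth.cpgs["linked_snp"].notna()]
        checked = 0
        for _, row in linked.iterrows():
            base = truth.baseline.loc[row["cpg_id"], "t"]
            eff = row["linked_effect"]
            for ind in truth.dosages.columns:
                d = truth.dosages.loc[row["linked_snp"], ind]
                expected = np.clip(base + eff * d, 0.0, 1.0)
                if 0.0 < expected < 1.0:
                    assert betas.loc[row["cpg_id"], f"{ind}_t"] == pytest.approx(expected, abs=1e-12)
                    checked += 1
        assert checked > 10
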