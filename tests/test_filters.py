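"""Filter cascade semantics: QC thresholds, annotation exclusions, carrier sets."""

import numpy as np
import pandas as pd
import pytest

from carrierscan.filters import (
    FilterConfig,
    GenotypeCall,
    VariantRecord,
    candidate_risk_mask,
    filter_log,
    first_failing_rule,
    genotype_qc_mask,
    is_candidate_risk,
    pass_genotype_qc,
    qualifying_variants,
)

CFG = FilterConfig()


def make_call(depth=50, vaf=0.5, gq=90, **kw):
    defaults = dict(sample_id="S1", variant_key="chr1:100:A:T", allele_count=1)
    defaults.update(kw)
    return GenotypeCall(depth=depth, vaf=vaf, gq=gq, **defaults)


def make_variant(**kw):
    defaults = dict(
        chrom="chr1", pos=100, ref="A", alt="T", gene="G1", csq="missense",
        aa_pos=10, af_pop=0.0, cadd_phred=25.0, sift="deleterious",
        pp2="probably_damaging",
    )
    defaults.update(kw)
    return VariantRecord(**defaults)


class TestGenotypeQc:
    @pytest.mark.parametrize(
        "depth,vaf,gq,expected",
        [
            (19, 0.5, 99, False),   # depth just below threshold
            (20, 0.30, 20, True),   # all three exactly at threshold: retained
            (50, 0.29, 90, False),
            (50, 0.5, 19, False),
            (np.nan, 0.5, 90, False),  # missing fields fail closed
        ],
    )
    def test_threshold_boundaries(self, depth, vaf, gq, expected):
        assert pass_genotype_qc(make_call(depth=depth, vaf=vaf, gq=gq), CFG) is expected

    def test_mask_matches_scalar_recount(self, rng):
        n = 10_000
        df = pd.DataFrame(
            {
                "sample_id": "S",
                "variant_key": "k",
                "allele_count": 1,
                "depth": rng.integers(0, 40, n),
                "vaf": rng.random(n),
                "gq": rng.integers(0, 40, n),
            }
        )
        mask = genotype_qc_mask(df, CFG)
        # independent triple-threshold re-count, call by call
        recount = sum(
            pass_genotype_qc(make_call(depth=float(d), vaf=float(v), gq=float(g)), CFG)
            for d, v, g in zip(df["depth"], df["vaf"], df["gq"])
        )
        assert int(mask.sum()) == recount


class TestCandidateRisk:
    def test_damaging_missense_passes(self):
        assert is_candidate_risk(make_variant(), CFG)

    def test_synonymous_always_fails(self):
        assert not is_candidate_risk(make_variant(csq="synonymous"), CFG)

    def test_af_boundary_is_common(self):
        # population frequency exactly at 0.1% counts as common
        assert not is_candidate_risk(make_variant(af_pop=0.001), CFG)
        assert is_candidate_risk(make_variant(af_pop=0.0009), CFG)

    def test_absent_frequency_counts_as_rare(self):
        assert is_candidate_risk(make_variant(af_pop=None), CFG)

    def test_cadd_boundary_strict(self):
        assert not is_candidate_risk(make_variant(cadd_phred=20.0), CFG)
        assert is_candidate_risk(make_variant(cadd_phred=20.01), CFG)

    def test_both_benign_excluded(self):
        assert not is_candidate_risk(make_variant(sift="tolerated", pp2="benign"), CFG)
        # one non-benign predictor is enough to keep the variant
        assert is_candidate_risk(make_variant(sift="tolerated", pp2="possibly_damaging"), CFG)

    def test_lof_passes_without_predictors(self):
        v = make_variant(csq="nonsense", cadd_phred=None, sift=None, pp2=None)
        assert is_candidate_risk(v, CFG)

    def test_missing_scores_fail_missense(self):
        assert not is_candidate_risk(make_variant(cadd_phred=None), CFG)

    def test_truth_table_oracle(self, rng):
        """Scalar predicate equals an exhaustive truth-table oracle."""
        csqs = ["missense", "nonsense", "synonymous"]
        afs = [None, 0.0, 0.0005, 0.001, 0.01]
        cadds = [None, 10.0, 20.0, 30.0]
        sifts = [None, "deleterious", "tolerated"]
        pp2s = [None, "probably_damaging", "benign"]
        for csq in csqs:
            for af in afs:
                for cadd in cadds:
                    for sift in sifts:
                        for pp2 in pp2s:
                            v = make_variant(csq=csq, af_pop=af, cadd_phred=cadd, sift=sift, pp2=pp2)
                            # oracle written straight from the rule statement
                            rare = af is None or af < 0.001
                            nonsilent = csq in ("missense", "nonsense")
                            if csq == "nonsense":
                                insilico = True
                            else:
                                insilico = (
                                    cadd is not None and cadd > 20.0
                                    and not (sift == "tolerated" and pp2 == "benign")
                                )
                            assert is_candidate_risk(v, CFG) == (rare and nonsilent and insilico)

    def test_strict_predictor_rule(self):
        strict = FilterConfig(predictor_rule="both")
        assert not is_candidate_risk(make_variant(sift="tolerated", pp2="possibly_damaging"), strict)
        assert is_candidate_risk(make_variant(sift="deleterious", pp2="possibly_damaging"), strict)


def _toy_cohort():
    variants = pd.DataFrame(
        {
            "variant_key": ["k1", "k2", "k3", "k4"],
            "chrom": "chr1", "pos": [1, 2, 3, 4], "ref": "A", "alt": "T",
            "gene": ["G1", "G1", "G2", "G2"],
            "csq": ["missense", "missense", "synonymous", "missense"],
            "aa_pos": [5, 6, 7, 8],
            "af_pop": [np.nan, 0.0, np.nan, 0.05],
            "cadd": [25.0, 30.0, 25.0, 25.0],
            "sift": "deleterious", "pp2": "probably_damaging",
        }
    )
    genotypes = pd.DataFrame(
        {
            "sample_id": ["S1", "S1", "S2", "S3", "S3"],
            "variant_key": ["k1", "k2", "k1", "k3", "k4"],
            "allele_count": 1,
            "depth": [50, 50, 15, 50, 50],
            "vaf": 0.5,
            "gq": 90,
        }
    )
    return variants, genotypes


class TestQualifyingVariants:
    def test_empty_genotypes_empty_carriers(self):
        variants, _ = _toy_cohort()
        empty = pd.DataFrame(columns=["sample_id", "variant_key", "allele_count", "depth", "vaf", "gq"])
        assert qualifying_variants(variants, empty, CFG).empty

    def test_sample_with_two_variants_counts_once(self):
        variants, genotypes = _toy_cohort()
        carr = qualifying_variants(variants, genotypes, CFG)
        s1 = carr[(carr["sample_id"] == "S1") & (carr["gene"] == "G1")]
        assert len(s1) == 1
        assert int(s1["n_qualifying_variants"].iloc[0]) == 2

    def test_qc_and_annotation_failures_excluded(self):
        variants, genotypes = _toy_cohort()
        carr = qualifying_variants(variants, genotypes, CFG)
        pairs = set(zip(carr["sample_id"], carr["gene"]))
        assert ("S2", "G1") not in pairs  # low depth
        assert ("S3", "G2") not in pairs  # synonymous + common
        assert pairs == {("S1", "G1")}

    def test_unknown_variant_key_raises(self):
        variants, genotypes = _toy_cohort()
        bad = genotypes.copy()
        bad.loc[0, "variant_key"] = "nope"
        with pytest.raises(ValueError, match="unknown variants"):
            qualifying_variants(variants, bad, CFG)


class TestCascadeProperties:
    def _random_tables(self, rng, n_var=60, n_calls=400):
        csq = rng.choice(["missense", "nonsense", "synonymous", "intronic"], n_var)
        variants = pd.DataFrame(
            {
                "variant_key": [f"k{i}" for i in range(n_var)],
                "chrom": "chr1", "pos": np.arange(1, n_var + 1),
                "ref": "A", "alt": "T",
                "gene": rng.choice([f"G{j}" for j in range(8)], n_var),
                "csq": csq,
                "aa_pos": rng.integers(1, 500, n_var),
                "af_pop": np.where(rng.random(n_var) < 0.3, np.nan, rng.uniform(0, 0.01, n_var)),
                "cadd": np.where(rng.random(n_var) < 0.2, np.nan, rng.uniform(0, 40, n_var)),
                "sift": rng.choice(["deleterious", "tolerated", ""], n_var),
                "pp2": rng.choice(["probably_damaging", "benign", ""], n_var),
            }
        )
        genotypes = pd.DataFrame(
            {
                "sample_id": rng.choice([f"S{j}" for j in range(30)], n_calls),
                "variant_key": rng.choice(variants["variant_key"], n_calls),
                "allele_count": rng.integers(1, 3, n_calls),
                "depth": rng.integers(0, 60, n_calls),
                "vaf": rng.random(n_calls),
                "gq": rng.integers(0, 99, n_calls),
            }
        ).drop_duplicates(["sample_id", "variant_key"], ignore_index=True)
        return variants, genotypes

    def test_filter_order_independence(self, rng):
        """QC-then-annotation equals annotation-then-QC."""
        variants, genotypes = self._random_tables(rng)
        qc_first = genotypes[genotype_qc_mask(genotypes, CFG)]
        keys = set(variants.loc[candidate_risk_mask(variants, CFG), "variant_key"])
        a = set(
            map(tuple, qc_first.loc[qc_first["variant_key"].isin(keys), ["sample_id", "variant_key"]].to_numpy())
        )
        ann_first = genotypes[genotypes["variant_key"].isin(keys)]
        b = set(
            map(tuple, ann_first.loc[genotype_qc_mask(ann_first, CFG), ["sample_id", "variant_key"]].to_numpy())
        )
        assert a == b

    def test_monotonicity_relaxing_never_shrinks(self, rng):
        variants, genotypes = self._random_tables(rng)
        base = qualifying_variants(variants, genotypes, CFG)
        base_pairs = set(zip(base["sample_id"], base["gene"]))
        relaxed_cfgs = [
            FilterConfig(depth_min=10),
            FilterConfig(vaf_min=0.2),
            FilterConfig(gq_min=10),
            FilterConfig(af_max=0.01),
            FilterConfig(cadd_min=10),
        ]
        for cfg in relaxed_cfgs:
            loose = qualifying_variants(variants, genotypes, cfg)
            assert base_pairs <= set(zip(loose["sample_id"], loose["gene"]))

    def test_conservation_one_rule_per_call(self, rng):
        """Every call is retained or attributed to exactly one first rule."""
        variants, genotypes = self._random_tables(rng)
        log = filter_log(variants, genotypes, CFG)
        assert len(log) == len(genotypes)
        rule = first_failing_rule(variants, genotypes, CFG)
        retained = rule == ""
        # retained == passes QC and annotation
        keys = set(variants.loc[candidate_risk_mask(variants, CFG), "variant_key"])
        expected = genotype_qc_mask(genotypes, CFG) & genotypes["variant_key"].isin(keys)
        assert (retained == expected).all()
        # QC rules take precedence and match the scalar predicates
        low_depth = rule == "low_depth"
        assert (low_depth == (pd.to_numeric(genotypes["depth"]) < CFG.depth_min)).all()
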