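"""Synthetic generators: references, reads, communities, CPUE."""

import numpy as np
import pandas as pd
import pytest

from edna_profiler import synth
from edna_profiler.synth import (CommunitySpec, ErrorModel,
                                 InfeasibleDivergence, generate_community,
                                 generate_cpue, generate_references,
                                 simulate_counts, simulate_reads)


def _dm(labels, entries):
    dm = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b, d in entries:
        dm.loc[a, b] = dm.loc[b, a] = d
    return dm


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestGenerateReferences:
    def test_identical_group_shares_sequence(self):
        dm = _dm(["A_sp", "B_sp", "C_sp"],
                 [("A_sp", "C_sp", 0.10), ("B_sp", "C_sp", 0.10)])
        db = generate_references(dm, identical_groups=[{"A_sp", "B_sp"}], seed=1)
        seqs = {s.species: s.sequence for s in db.sequences}
        assert seqs["A_sp"] == seqs["B_sp"]
        assert seqs["A_sp"] != seqs["C_sp"]

    def test_realized_divergence_matches_target(self):
        dm = _dm(["A_sp", "B_sp"], [("A_sp", "B_sp", 0.02)])
        db = generate_references(dm, length=98, seed=2)
        seqs = [s.sequence for s in db.sequences]
        assert abs(_hamming(*seqs) - round(0.02 * 98)) <= 2

    def test_tree_additive_matrix_realized_exactly(self):
        dm = _dm(["A_sp", "B_sp", "C_sp"],
                 [("A_sp", "B_sp", 0.02), ("A_sp", "C_sp", 0.08),
                  ("B_sp", "C_sp", 0.10)])
        db = generate_references(dm, seed=3)
        seqs = {s.species: s.sequence for s in db.sequences}
        for a, b in [("A_sp", "B_sp"), ("A_sp", "C_sp"), ("B_sp", "C_sp")]:
            assert abs(_hamming(seqs[a], seqs[b]) - round(dm.loc[a, b] * 98)) <= 2

    def test_infeasible_triangle_raises(self):
        dm = _dm(["A_sp", "B_sp", "C_sp"],
                 [("A_sp", "B_sp", 0.02), ("A_sp", "C_sp", 0.08),
                  ("B_sp", "C_sp", 0.30)])
        with pytest.raises(InfeasibleDivergence):
            generate_references(dm, seed=3)

    def test_deterministic_under_seed(self):
        dm = _dm(["A_sp", "B_sp"], [("A_sp", "B_sp", 0.05)])
        db1 = generate_references(dm, seed=7, accession_counts={"A_sp": 2})
        db2 = generate_references(dm, seed=7, accession_counts={"A_sp": 2})
        assert [(s.accession, s.sequence) for s in db1.sequences] == \
            [(s.accession, s.sequence) for s in db2.sequences]

    def test_extra_accessions_at_intra_divergence(self):
        dm = _dm(["A_sp", "B_sp"], [("A_sp", "B_sp", 0.10)])
        db = generate_references(dm, seed=4, accession_counts={"A_sp": 3})
        a_seqs = [s.sequence for s in db.sequences if s.species == "A_sp"]
        assert len(a_seqs) == 3
        assert all(_hamming(a_seqs[0], s) == 1 for s in a_seqs[1:])


class TestSimulateReads:
    def test_zero_error_model_copies_reference(self):
        model = ErrorModel([0.0])
        reads = simulate_reads("ACGT" * 25, n=50, model=model, seed=1)
        assert all(seq == "ACGT" * 25 for _, seq in reads)

    def test_mean_substitutions_match_poisson_binomial_expectation(self):
        model = ErrorModel.study_default(indel_fraction=0.0)
        L = 98
        template = "ACGT" * 25
        template = template[:L]
        reads = simulate_reads(template, n=10000, model=model, seed=9)
        p = model.rate(np.arange(1, L + 1))
        subs = [_hamming(template, seq) for _, seq in reads]
        expect = p.sum()
        se = np.sqrt((p * (1 - p)).sum() / len(reads))
        assert expect == pytest.approx(98 * (0.0066 + 0.0296) / 2, rel=1e-6)
        assert abs(np.mean(subs) - expect) < 3 * se

    def test_no_indels_means_length_preserved(self):
        model = ErrorModel.study_default(indel_fraction=0.0)
        reads = simulate_reads("ACGT" * 25, n=500, model=model, seed=2)
        assert all(len(seq) == 100 for _, seq in reads)

    def test_indels_change_length(self):
        model = ErrorModel([0.05], indel_fraction=1.0)
        reads = simulate_reads("ACGT" * 25, n=200, model=model, seed=2)
        assert any(len(seq) != 100 for _, seq in reads)

    def test_n_nonpositive_errors(self):
        with pytest.raises(ValueError):
            simulate_reads("ACGT" * 25, n=0, model=ErrorModel([0.0]))

    def test_deterministic(self):
        model = ErrorModel.study_default()
        r1 = simulate_reads("ACGT" * 25, n=100, model=model, seed=5)
        r2 = simulate_reads("ACGT" * 25, n=100, model=model, seed=5)
        assert r1 == r2


class TestErrorModelObject:
    def test_rate_clipped_to_unit_interval(self):
        m = ErrorModel([-0.5, 0.02])
        r = m.rate(np.arange(1, 200))
        assert r.min() >= 0 and r.max() <= 1

    def test_linear_endpoints(self):
        m = ErrorModel.linear(0.0066, 0.0296, 98)
        assert m.rate([1])[0] == pytest.approx(0.0066)
        assert m.rate([98])[0] == pytest.approx(0.0296)

    def test_roundtrip_dict(self):
        m = ErrorModel.study_default()
        assert ErrorModel.from_dict(m.to_dict()).coefficients == m.coefficients

    def test_child_seeds_independent_by_label(self):
        a = synth.child_rng(1, "alpha").random(4)
        b = synth.child_rng(1, "beta").random(4)
        assert not np.allclose(a, b)


def _toy_spec(**kw):
    ab = {"S1": {"Sp_a": 0.6, "Sp_b": 0.4}, "S2": {"Sp_a": 0.5, "Sp_b": 0.5},
          "NEG": {}}
    defaults = dict(species_abundances=ab,
                    n_reads={"S1": 2000, "S2": 2000, "NEG": 0}, seed=3)
    defaults.update(kw)
    return CommunitySpec(**defaults)


class TestCommunity:
    def test_truth_marginals_equal_configured_reads(self):
        truth, observed = simulate_counts(_toy_spec())
        assert truth["S1"].sum() == 2000 and truth["S2"].sum() == 2000
        assert truth.equals(observed)  # no crosstalk configured

    def test_crosstalk_relocation_rate(self):
        # one loaded library and one empty receiver, so every hop is visible
        spec = _toy_spec(
            species_abundances={"S1": {"Sp_a": 1.0}, "EMPTY": {}},
            n_reads={"S1": 1_000_000, "EMPTY": 0},
            crosstalk_rate=1e-4)
        truth, observed = simulate_counts(spec)
        moved = int(observed.loc["Sp_a", "EMPTY"])
        expect = 1e6 * 1e-4
        assert truth.loc["Sp_a", "EMPTY"] == 0
        assert abs(moved - expect) < 3 * np.sqrt(expect)

    def test_negative_control_spike_dominates(self, watershed_db):
        spec = synth.watershed_community_spec(
            watershed_db, seed=2, reads_per_sample=500)
        truth, _ = simulate_counts(spec)
        neg = truth["NEG01"]
        assert neg.idxmax() == "Salmo_fictus" and neg.max() == 500
        assert truth["NEG02"].sum() == 0

    def test_negative_with_abundance_rejected(self):
        spec = _toy_spec(sample_types={"NEG": "negative"},
                         species_abundances={"S1": {"Sp_a": 1.0},
                                             "S2": {"Sp_a": 1.0},
                                             "NEG": {"Sp_a": 1.0}})
        with pytest.raises(ValueError, match="negative control"):
            spec.validate()

    def test_dropout_frequency(self):
        n_pairs = 40
        ab = {}
        reads = {}
        pairs = []
        for i in range(n_pairs):
            for suffix in ("a", "b"):
                s = f"P{i}{suffix}"
                ab[s] = {f"Sp_{j}": 0.2 for j in range(5)}
                reads[s] = 100
            pairs.append((f"P{i}a", f"P{i}b"))
        spec = CommunitySpec(species_abundances=ab, n_reads=reads,
                             replicate_pairs=pairs, dropout_prob=0.2, seed=8)
        truth, _ = simulate_counts(spec)
        dropouts = 0
        for a, b in pairs:
            for sp in truth.index:
                if (truth.loc[sp, a] == 0) != (truth.loc[sp, b] == 0):
                    dropouts += 1
        n_trials = n_pairs * 5
        se = np.sqrt(0.2 * 0.8 / n_trials)
        assert abs(dropouts / n_trials - 0.2) < 3 * se

    def test_generate_community_reads_match_truth(self, watershed_db):
        spec = synth.watershed_community_spec(
            watershed_db, seed=4, reads_per_sample=300, crosstalk_rate=0.0,
            spike_reads=0, n_biological=4, n_replicate_pairs=0, n_negative=1)
        comm = generate_community(watershed_db, spec)
        for s in comm.reads:
            by_species = {}
            for rid, _ in comm.reads[s]:
                sp = comm.source[rid][0]
                by_species[sp] = by_species.get(sp, 0) + 1
            for sp, c in by_species.items():
                assert comm.truth.loc[sp, s] == c

    def test_unknown_species_rejected(self, watershed_db):
        spec = _toy_spec()
        with pytest.raises(ValueError, match="not in reference DB"):
            generate_community(watershed_db, spec)


class TestCPUE:
    def test_zero_noise_is_proportional(self):
        totals = pd.Series({f"Sp_{i}": 10.0 * (i + 1) for i in range(8)})
        cpue = generate_cpue(totals, noise_sd=0.0, seed=1).set_index("taxon")["cpue"]
        ratio = cpue / totals
        assert np.allclose(ratio, ratio.iloc[0])

    def test_deterministic(self):
        totals = {"Sp_a": 5.0, "Sp_b": 50.0}
        t1 = generate_cpue(totals, noise_sd=0.5, seed=3)
        t2 = generate_cpue(totals, noise_sd=0.5, seed=3)
        assert t1.equals(t2)

    def test_nonpositive_totals_rejected(self):
        with pytest.raises(ValueError):
            generate_cpue({"Sp_a": 0.0}, seed=1)

    def test_log_log_correlation_significant_across_seeds(self):
        """Monte Carlo: 30 lognormal taxa at noise_sd 0.5 give a significant
        positive log-log correlation in >=95% of 200 seeds."""
        from scipy import stats

        rng = np.random.default_rng(123)
        hits = 0
        for seed in range(200):
            totals = pd.Series(np.exp(rng.normal(3, 1.3, size=30)),
                               index=[f"Sp_{i}" for i in range(30)])
            cpue = generate_cpue(totals, noise_sd=0.5, seed=seed)
            r, p = stats.pearsonr(np.log(cpue["cpue"]), np.log(totals.values))
            hits += (r > 0) and (p < 0.05)
        assert hits >= 0.95 * 200
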