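
import pytest
from sklearn.metrics import adjusted_rand_score

from ibcpipe.clonal import (
    CloneCluster,
    classify_evolution,
    compute_ccf,
    dp_cluster,
    records_for_pair,
    shared_mutation_fraction,
)
from ibcpipe.copy_number import AlleleSegment
from ibcpipe.errors import DomainError
from ibcpipe.synthdata import SimulationConfig, simulate_cohort

from conftest import make_planted_records, partition_labels


class FakeVariant:
    def __init__(self, alt_depth, total_depth, chromosome="chr1", position=500,
                 ref="C", alt="T"):
        self.chromosome = chromosome
        self.position = position
        self.ref = ref
        self.alt = alt
        self.alt_depth = alt_depth
        self.total_depth = total_depth

    @property
    def key(self):
        return (self.chromosome, self.position, self.ref, self.alt)


DIPLOID = AlleleSegment("chr1", 1, 1000, 1, 1)


class TestComputeCcf:
    def test_pure_diploid_clonal(self):
        rec = compute_ccf(FakeVariant(500, 1000), DIPLOID, purity=1.0)
        assert rec.mutation_copy_number == pytest.approx(1.0)
        assert rec.multiplicity == 1
        assert rec.ccf == pytest.approx(1.0)

    def test_half_purity_clonal(self):
        # vaf 0.25 at purity 0.5, CN 2: nmut = 0.25 * 2 / 0.5 = 1.0
        rec = compute_ccf(FakeVariant(250, 1000), DIPLOID, purity=0.5)
        assert rec.ccf == pytest.approx(1.0)

    def test_half_purity_subclonal(self):
        # vaf 0.125 -> nmut 0.5 -> ccf 0.5
        rec = compute_ccf(FakeVariant(125, 1000), DIPLOID, purity=0.5)
        assert rec.ccf == pytest.approx(0.5)

    def test_variant_outside_segment_rejected(self):
        seg = AlleleSegment("chr2", 1, 100, 1, 1)
        with pytest.raises(DomainError):
            compute_ccf(FakeVariant(10, 100), seg, purity=0.5)

    @pytest.mark.parametrize("purity,major,minor,m,phi", [
        ("1", 1, 1, 1, "1"),
        ("1/2", 1, 1, 1, "1/2"),
        ("1/4", 2, 1, 1, "4/5"),
        ("4/5", 2, 2, 2, "3/4"),
        ("3/5", 3, 1, 2, "9/10"),
        ("2/5", 2, 0, 1, "1/4"),
    ])
    def test_generative_roundtrip_at_infinite_depth(self, purity, major, minor, m, phi):
        """Computing the model VAF and inverting it recovers phi exactly when
        the read counts carry no sampling noise (multiplicity is only
        identifiable when m*phi > 1 rules out the smaller-m explanation,
        which these cases satisfy)."""
        from fractions import Fraction as F

        purity, phi = F(purity), F(phi)
        cnt = major + minor
        vaf = purity * m * phi / (purity * cnt + 2 * (1 - purity))
        k = max(10_000_000 // vaf.denominator, 1)
        seg = AlleleSegment("chr1", 1, 1000, major, minor)
        rec = compute_ccf(FakeVariant(vaf.numerator * k, vaf.denominator * k),
                          seg, purity=float(purity))
        assert rec.multiplicity == m
        assert rec.ccf == pytest.approx(float(phi), abs=1e-9)


class TestDpCluster:
    def test_single_clonal_cluster(self):
        records, _ = make_planted_records([(1.0, 1.0)], 50, seed=1)
        retained, excluded = dp_cluster(records, iterations=1500, burn_in=750, seed=1)
        assert len(retained) == 1
        assert excluded == []
        assert retained[0].mean_ccf["pre"] == pytest.approx(1.0, abs=0.05)
        assert retained[0].mean_ccf["post"] == pytest.approx(1.0, abs=0.05)

    def test_two_cluster_recovery(self):
        """Planted clusters at CCF 1.0 and 0.3 (50+50 mutations, depth 400)
        are recovered with ARI >= 0.9 and means within 0.05."""
        records, labels = make_planted_records([(1.0, 1.0), (0.3, 0.3)], 50, seed=7)
        retained, excluded = dp_cluster(records, iterations=5000, burn_in=2500, seed=7)
        assert len(retained) == 2
        keys = sorted(records)
        ari = adjusted_rand_score([labels[k] for k in keys],
                                  partition_labels(retained + excluded, keys))
        assert ari >= 0.9
        means = sorted(c.mean_ccf["pre"] for c in retained)
        assert means[0] == pytest.approx(0.3, abs=0.05)
        assert means[1] == pytest.approx(1.0, abs=0.05)

    def test_small_cluster_excluded(self):
        """A planted 3-mutation cluster lands in the excluded list."""
        records, _ = make_planted_records([(1.0, 1.0), (0.3, 0.3)], 30, seed=3)
        extra, _ = make_planted_records([(0.6, 0.6)], 3, seed=9, chrom="chr2")
        records.update(extra)
        retained, excluded = dp_cluster(records, iterations=3000, burn_in=1500, seed=11)
        assert sorted(c.size for c in retained) == [30, 30]
        assert [c.size for c in excluded] == [3]
        assert set(excluded[0].members) == set(extra)

    def test_too_few_mutations_all_excluded(self):
        records, _ = make_planted_records([(1.0, 1.0)], 3, seed=2)
        retained, excluded = dp_cluster(records, iterations=100, burn_in=50, seed=2)
        assert retained == []
        assert len(excluded) == 1

    def test_root_clone_recovered_from_simulated_patient(self):
        """The truncal cluster of a simulated branched patient is recovered
        with CCF >= 0.9 in both biopsies."""
        cfg = SimulationConfig(
            n_patients=1, seed=21, evolution_modes=["branched"],
            truncal_mutations_mean=30, subclone_mutations_mean=15,
            indel_fraction=0.0, purity_range=(0.6, 0.9))
        bundle = simulate_cohort(cfg)
        pre, post = bundle.samples

        class V:
            def __init__(self, key, reads):
                self.chromosome, self.position, self.ref, self.alt = key
                self.alt_depth, self.total_depth = reads
                self.key = key

        pre_vs = [V(k, r) for k, r in pre.reads.items()]
        post_vs = [V(k, r) for k, r in post.reads.items()]
        records = records_for_pair(pre_vs, post_vs, pre.segments, post.segments,
                                   pre.purity, post.purity)
        retained, _ = dp_cluster(records, iterations=1500, burn_in=750, seed=5)
        assert any(c.mean_ccf["pre"] >= 0.9 and c.mean_ccf["post"] >= 0.9
                   for c in retained)


class TestEvolutionClassification:
    def mk(self, cid, pre, post):
        return CloneCluster(cid, [("chr1", i, "C", "T") for i in range(4)],
                            {"pre": pre, "post": post})

    def test_branched(self):
        clusters = [self.mk(1, 1.0, 1.0), self.mk(2, 0.4, 0.0), self.mk(3, 0.0, 0.5)]
        call = classify_evolution(clusters)
        assert call.pattern == "branched"
        events = {cid: ev for cid, _, _, ev in call.evidence}
        assert events == {1: "stable", 2: "lost", 3: "new"}

    def test_clonal_shift(self):
        """Subclonal expansions without appearance or disappearance (e.g.
        2% -> 38% and 22% -> 81%) classify as a clonal shift."""
        clusters = [self.mk(1, 0.96, 0.78), self.mk(2, 0.02, 0.38),
                    self.mk(3, 0.22, 0.81)]
        call = classify_evolution(clusters)
        assert call.pattern == "clonal_shift"
        events = {cid: ev for cid, _, _, ev in call.evidence}
        assert events[2] == "expanded" and events[3] == "expanded"

    def test_stable(self):
        clusters = [self.mk(1, 1.0, 1.0), self.mk(2, 0.3, 0.31)]
        assert classify_evolution(clusters).pattern == "stable"

    def test_missing_sample_rejected(self):
        bad = CloneCluster(1, [("chr1", 1, "C", "T")] * 4, {"pre": 0.5})
        with pytest.raises(DomainError):
            classify_evolution([bad])


class TestSharedFraction:
    def test_identical_sets(self):
        keys = [("chr1", i, "C", "T") for i in range(5)]
        assert shared_mutation_fraction(keys, keys) == 1.0

    def test_disjoint_sets(self):
        a = [("chr1", i, "C", "T") for i in range(5)]
        b = [("chr2", i, "C", "T") for i in range(5)]
        assert shared_mutation_fraction(a, b) == 0.0

    def test_empty_post_rejected(self):
        with pytest.raises(DomainError):
            shared_mutation_fraction([("chr1", 1, "C", "T")], [])

    def test_branched_fixture_matches_truth(self, small_bundle):
        """Shared fraction on simulated truth equals the clone-CCF algebra."""
        for patient in small_bundle.patients:
            pre = next(s for s in small_bundle.samples
                       if s.patient == patient.patient and s.timepoint == "pre")
            post = next(s for s in small_bundle.samples
                        if s.patient == patient.patient and s.timepoint == "post")
            observed = shared_mutation_fraction(pre.reads.keys(), post.reads.keys())
            ccf = {c.clone_id: c.ccf for c in patient.tree.clones}
            n_post = sum(1 for m in patient.mutations if ccf[m.clone_id]["post"] > 0)
            n_shared = sum(1 for m in patient.mutations
                           if ccf[m.clone_id]["post"] > 0 and ccf[m.clone_id]["pre"] > 0)
            assert observed == pytest.approx(n_shared / n_post)
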