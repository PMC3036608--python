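from __future__ import annotations

import hashlib

import numpy as np
import pytest

from phytoscan.motif import compile_pattern, scan_promoter, screen
from phytoscan.physiology import compare_groups, transfer_percent
from phytoscan.qpcr import ddct
from phytoscan.synthetic import (
    ARABIDOPSIS_COMPOSITION,
    TRANSFER_MINUS_PI_SHOOT_TO_ROOT,
    GroupSpec,
    PlantedSiteSpec,
    QpcrDesignSpec,
    SyntheticError,
    synth_groups,
    synth_promoters,
    synth_qpcr,
    synth_tracer,
    write_truth_tsv,
)


def _hash_records(records) -> str:
    h = hashlib.sha256()
    for r in records:
        h.update(f"{r.gene_model_id}:{r.sequence}\n".encode())
    return h.hexdigest()


class TestSynthPromoters:
    def test_planted_distance_convention(self, p1bs):
        recs, truth = synth_promoters(
            1,
            length=500,
            planted=[PlantedSiteSpec(0, 432, "+", word="GGATATTC")],
            seed=1,
            base_composition={"C": 0.5, "G": 0.5},
        )
        (hit,) = scan_promoter(recs[0], p1bs)
        assert hit.upstream_distance == 432
        assert hit.matched_sequence == "GGATATTC"
        assert truth[0]["upstream_distance"] == 432

    def test_empty(self):
        recs, truth = synth_promoters(0, seed=1)
        assert recs == [] and truth == []

    def test_determinism_and_seed_sensitivity(self):
        a, _ = synth_promoters(20, seed=42)
        b, _ = synth_promoters(20, seed=42)
        c, _ = synth_promoters(20, seed=43)
        assert _hash_records(a) == _hash_records(b)
        assert _hash_records(a) != _hash_records(c)

    def test_minus_strand_planting(self, p1bs):
        recs, _ = synth_promoters(
            1,
            length=100,
            planted=[PlantedSiteSpec(0, 50, "-", word="GCATATAC")],
            seed=3,
            base_composition={"C": 0.5, "G": 0.5},
        )
        hits = scan_promoter(recs[0], p1bs)
        dists = {h.upstream_distance for h in hits}
        assert 50 in dists

    def test_full_recall_zero_false_positives_on_cg_background(self, p1bs):
        rng = np.random.default_rng(17)
        n, length = 200, 500
        planted_idx = sorted(rng.choice(n, size=50, replace=False))
        specs = [
            PlantedSiteSpec(int(i), int(rng.integers(p1bs.k, length + 1)))
            for i in planted_idx
        ]
        recs, truth = synth_promoters(
            n, length=length, planted=specs, seed=18,
            base_composition={"C": 0.5, "G": 0.5},
        )
        result = screen(recs, p1bs)
        planted_ids = {t["gene_model_id"] for t in truth}
        assert set(result.hits) == planted_ids  # recall and no false positives
        by_id = {t["gene_model_id"]: t for t in truth}
        for gid, hits in result.hits.items():
            assert len(hits) == 1
            assert hits[0].upstream_distance == by_id[gid]["upstream_distance"]

    def test_overlapping_planted_sites_error(self):
        with pytest.raises(SyntheticError, match="overlap"):
            synth_promoters(
                1, length=100,
                planted=[PlantedSiteSpec(0, 50), PlantedSiteSpec(0, 54)],
                seed=1,
            )

    def test_bad_composition(self):
        with pytest.raises(SyntheticError, match="sum"):
            synth_promoters(1, base_composition={"A": 0.9}, seed=1)

    def test_word_must_match_pattern(self):
        with pytest.raises(SyntheticError, match="does not match"):
            synth_promoters(
                1, planted=[PlantedSiteSpec(0, 100, word="AAAAAAAA")], seed=1
            )

    def test_arabidopsis_composition_shifts_gc(self):
        recs, _ = synth_promoters(
            30, base_composition=ARABIDOPSIS_COMPOSITION, seed=5
        )
        gc = sum(s.sequence.count("G") + s.sequence.count("C") for s in recs)
        total = sum(len(s) for s in recs)
        assert 0.3 < gc / total < 0.42

    def test_truth_tsv(self, tmp_path):
        _, truth = synth_promoters(
            2, planted=[PlantedSiteSpec(0, 200, word="GGATATTC")], seed=1
        )
        out = tmp_path / "truth.tsv"
        write_truth_tsv(truth, out)
        lines = out.read_text().strip().split("\n")
        assert lines[1].split("\t") == ["SYN0000.1", "200", "+", "GGATATTC"]


FIG2_GRID = tuple(
    (geno, tissue, treat)
    for geno in ("WT", "phr1")
    for tissue in ("root", "shoot")
    for treat in ("complete", "-Pi", "+Phi", "-S")
)


class TestSynthQpcr:
    def test_noiseless_null(self):
        spec = QpcrDesignSpec(
            conditions=FIG2_GRID, genes=("SULTR1;3",), true_effects={},
            n_bio=2, seed=0,
        )
        records, _ = synth_qpcr(spec)
        for r in ddct(records, "SULTR1;3"):
            assert r.log2_rq == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_effect_recovered_exactly(self):
        spec = QpcrDesignSpec(
            conditions=FIG2_GRID, genes=("SULTR1;3",),
            true_effects={("SULTR1;3", "WT", "root", "-Pi"): 2.0},
            n_bio=2, seed=0,
        )
        records, _ = synth_qpcr(spec)
        res = {(r.genotype, r.tissue, r.treatment): r.log2_rq
               for r in ddct(records, "SULTR1;3")}
        assert res[("WT", "root", "-Pi")] == pytest.approx(2.0, abs=1e-12)
        assert res[("phr1", "shoot", "+Phi")] == pytest.approx(0.0, abs=1e-12)

    def test_calibrator_effect_must_be_zero(self):
        with pytest.raises(SyntheticError, match="calibrator"):
            QpcrDesignSpec(
                conditions=FIG2_GRID, genes=("G",),
                true_effects={("G", "WT", "root", "complete"): 1.0},
            )

    def test_noisy_recovery_within_3se(self):
        effects = {
            ("SULTR1;3", "WT", "root", "-Pi"): 3.0,
            ("SULTR1;3", "WT", "shoot", "-Pi"): 2.0,
            ("SULTR1;3", "phr1", "root", "-Pi"): 1.0,
        }
        spec = QpcrDesignSpec(
            conditions=FIG2_GRID, genes=("SULTR1;3",), true_effects=effects,
            ref_drift_sd=0.3, technical_sd=0.15, biological_sd=0.2,
            n_bio=3, seed=77,
        )
        records, truth = synth_qpcr(spec)
        # oracle SE from generator parameters: per-replicate dCT variance is
        # bio^2 + 2*tech^2/n_tech; estimate averages n_bio replicates and
        # subtracts an independent calibrator mean of n_bio replicates
        var_dct = spec.biological_sd**2 + 2 * spec.technical_sd**2 / spec.n_tech
        se = np.sqrt(var_dct / spec.n_bio + var_dct / spec.n_bio)
        for r in ddct(records, "SULTR1;3"):
            true = truth[("SULTR1;3", r.genotype, r.tissue, r.treatment)]
            if (r.genotype, r.treatment) == ("WT", "complete"):
                continue  # calibrator: zero by construction
            assert abs(r.log2_rq - true) < 3 * se

    def test_determinism(self):
        spec = QpcrDesignSpec(
            conditions=FIG2_GRID[:4], genes=("G",), true_effects={},
            ref_drift_sd=0.3, technical_sd=0.1, biological_sd=0.2, seed=5,
        )
        a, _ = synth_qpcr(spec)
        b, _ = synth_qpcr(spec)
        assert a == b


class TestSynthGroups:
    def test_sd_zero_gives_means(self):
        specs = [GroupSpec("a", 5.0, 0.0, 4), GroupSpec("b", 2.0, 0.0, 3)]
        vals = synth_groups(specs, seed=1)
        assert np.allclose(vals["a"], 5.0) and np.allclose(vals["b"], 2.0)

    def test_truncation_at_zero(self):
        specs = [GroupSpec("a", 0.1, 5.0, 100)]
        vals = synth_groups(specs, seed=2)
        assert (vals["a"] >= 0).all()
        assert (vals["a"] == 0).any()  # truncation actually occurred

    def test_determinism(self):
        specs = [GroupSpec("a", 1.0, 0.5, 10)]
        assert np.array_equal(
            synth_groups(specs, seed=3)["a"], synth_groups(specs, seed=3)["a"]
        )

    def test_invalid_specs(self):
        with pytest.raises(SyntheticError):
            GroupSpec("a", 1.0, -0.1, 4)
        with pytest.raises(SyntheticError):
            GroupSpec("a", 1.0, 0.1, 1)

    def test_table_parameterized_detection_seed0(self):
        specs = [
            GroupSpec(label=lab, mean=m, sd=s, n=4)
            for lab, (m, s) in TRANSFER_MINUS_PI_SHOOT_TO_ROOT.items()
        ]
        comp = compare_groups(synth_groups(specs, seed=0), reference="WT")
        assert set(comp.flagged()) == {"phr1", "sultr1;3"}

    def test_synth_tracer_round_trip(self):
        specs = [
            GroupSpec(label=lab, mean=m, sd=s, n=4)
            for lab, (m, s) in TRANSFER_MINUS_PI_SHOOT_TO_ROOT.items()
        ]
        ms = synth_tracer(specs, seed=4)
        raw = synth_groups(specs, seed=4)
        got = {}
        for m in ms:
            got.setdefault(m.genotype, []).append(transfer_percent(m))
        for lab in raw:
            assert np.allclose(sorted(got[lab]), sorted(raw[lab]))
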