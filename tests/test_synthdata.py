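"""Synthetic fixture generation, determinism, file round trips, CLI."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from nearcoding import io
from nearcoding.burden import fisher_burden, prune_related
from nearcoding.cli import main as cli_main
from nearcoding.regions import PromoterConfig, derive_promoter
from nearcoding.synthdata import (
    CohortSpec,
    FixtureSpec,
    make_fixture,
    make_genome_and_transcripts,
    genome_as_str,
    simulate_cohort,
)


class TestGeneratorDeterminism:
    def test_same_seed_identical_outputs(self, tmp_path):
        dirs = []
        for name in ("a", "b"):
            out = tmp_path / name
            out.mkdir()
            genome, transcripts, ccres, fixture = make_fixture(FixtureSpec(seed=5))
            io.write_fasta(genome, out / "genome.fa")
            io.write_gff3(transcripts, out / "transcripts.gff3")
            io.write_ccre_bed(ccres, out / "ccres.bed")
            io.write_vcf(
                fixture.variants, {c: len(s) for c, s in genome.items()},
                out / "variants.vcf",
            )
            dirs.append(out)
        for fname in ("genome.fa", "transcripts.gff3", "ccres.bed", "variants.vcf"):
            assert filecmp.cmp(dirs[0] / fname, dirs[1] / fname, shallow=False), fname

    def test_different_seeds_differ(self):
        g1, *_ = make_genome_and_transcripts(FixtureSpec(seed=1))
        g2, *_ = make_genome_and_transcripts(FixtureSpec(seed=2))
        assert bytes(g1["chr1"]) != bytes(g2["chr1"])


class TestPromoterPlacement:
    def test_no_ccres_all_promoters_use_p75_fallback(self):
        spec = FixtureSpec(seed=3, fraction_with_ccre=0.0)
        _, transcripts, ccres = make_genome_and_transcripts(spec)
        assert ccres == []
        cfg = PromoterConfig()
        for tx in transcripts:
            s, e = derive_promoter(tx, [], cfg)
            assert e - s == cfg.up_p75 + cfg.down_p75

    def test_all_ccres_cover_every_tss(self):
        spec = FixtureSpec(seed=3, fraction_with_ccre=1.0)
        _, transcripts, ccres = make_genome_and_transcripts(spec)
        assert len(ccres) == len(transcripts)
        cfg = PromoterConfig()
        for tx in transcripts:
            overlapping = [c for c in ccres if c.start <= tx.tss < c.end]
            assert overlapping
            # a sufficient element is returned exactly; deficient ones extended
            s, e = derive_promoter(tx, ccres, cfg)
            c = overlapping[0]
            if tx.strand == "+":
                up, down = tx.tss - c.start, c.end - tx.tss
            else:
                up, down = c.end - (tx.tss + 1), (tx.tss + 1) - c.start
            if up >= cfg.up_p25 and down >= cfg.down_p25:
                assert (s, e) == (c.start, c.end)
            else:
                assert e - s >= min(up, cfg.up_p25) + min(down, cfg.down_p25)


class TestPlantedTruth:
    def test_construction_verifies_on_multiple_seeds(self):
        for seed in (0, 11, 42):
            _, _, _, fixture = make_fixture(FixtureSpec(seed=seed))
            assert len(fixture.truth) == len(fixture.variants)

    def test_empty_planted_effects_retains_nothing(self):
        spec = FixtureSpec(seed=1, planted_effects=(("benign_background", 3),))
        _, _, _, fixture = make_fixture(spec)
        assert all(not t.expected_retained["de_novo"] for t in fixture.truth.values())


class TestCohortSimulation:
    def test_related_pairs_prunable(self):
        spec = FixtureSpec(seed=2)
        tables = simulate_cohort(spec)
        ids = list(tables.participants["participant_id"])
        kept = prune_related(
            ids, list(tables.king_pairs.itertuples(index=False, name=None)), seed=0
        )
        assert len(ids) - len(kept) >= spec.cohort.related_pairs

    def test_null_cohort_odds_ratio_centred_at_one(self):
        ors = []
        for seed in range(40):
            spec = FixtureSpec(
                seed=seed,
                cohort=CohortSpec(
                    n_cases=400, n_controls=400,
                    carrier_p_case=0.10, carrier_p_control=0.10,
                    related_pairs=0,
                ),
            )
            t = simulate_cohort(spec)
            merged = t.participants.merge(t.carriers, on="participant_id")
            r = fisher_burden(
                merged[merged["is_case"]]["carrier"],
                merged[~merged["is_case"]]["carrier"],
                compute_ci=False,
            )
            if not r.degenerate and np.isfinite(r.odds_ratio):
                ors.append(r.odds_ratio)
        assert 0.85 < np.median(ors) < 1.18

    def test_empty_case_arm_refused(self):
        spec = FixtureSpec(seed=1, cohort=CohortSpec(n_cases=0, related_pairs=0))
        t = simulate_cohort(spec)
        merged = t.participants.merge(t.carriers, on="participant_id")
        with pytest.raises(ValueError):
            fisher_burden(
                merged[merged["is_case"]]["carrier"],
                merged[~merged["is_case"]]["carrier"],
            )


class TestRoundTrips:
    def test_gff3_roundtrip(self, tmp_path, default_fixture):
        _, transcripts, _, _ = default_fixture
        path = tmp_path / "tx.gff3"
        io.write_gff3(transcripts, path)
        back = io.read_gff3(path)
        assert len(back) == len(transcripts)
        by_id = {t.transcript_id: t for t in back}
        for tx in transcripts:
            got = by_id[tx.transcript_id]
            assert got.exons == tx.exons
            assert got.strand == tx.strand
            assert (got.cds_start, got.cds_end) == (tx.cds_start, tx.cds_end)

    def test_vcf_roundtrip(self, tmp_path, default_fixture):
        genome, _, _, fixture = default_fixture
        path = tmp_path / "v.vcf"
        contigs = {c: len(s) for c, s in genome.items()}
        io.write_vcf(fixture.variants, contigs, path)
        back = io.read_vcf(path)
        assert list(back["variant_id"]) == list(fixture.variants["variant_id"])
        assert list(back["pos"]) == list(fixture.variants["pos"])
        orig = fixture.variants.set_index("variant_id")
        for rec in back.itertuples():
            assert rec.ref == orig.at[rec.variant_id, "ref"]
            if not pd.isna(rec.spliceai_max):
                assert rec.spliceai_max == pytest.approx(
                    orig.at[rec.variant_id, "spliceai_max"], rel=1e-6
                )

    def test_track_bed_roundtrip(self, tmp_path, default_fixture):
        *_, fixture = default_fixture
        path = tmp_path / "tracks.bed"
        io.write_track_bed(fixture.track_elements, path)
        back = io.read_track_bed(path)
        assert len(back) == len(fixture.track_elements)
        for a, b in zip(
            sorted(back, key=lambda e: e.start),
            sorted(fixture.track_elements, key=lambda e: e.start),
        ):
            assert (a.chrom, a.start, a.end, a.track) == (b.chrom, b.start, b.end, b.track)


class TestCli:
    def test_simulate_build_regions_prioritize(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "fix"
        res = runner.invoke(cli_main, ["simulate", "--seed", "4", "--out-dir", str(out)])
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli_main,
            [
                "build-regions",
                "--gff", str(out / "transcripts.gff3"),
                "--ccre", str(out / "ccres.bed"),
                "--out", str(tmp_path / "regions.bed"),
            ],
        )
        assert res.exit_code == 0, res.output
        rebuilt = io.read_regions_bed(tmp_path / "regions.bed")
        original = io.read_regions_bed(out / "regions.bed")
        assert {(r.chrom, r.start, r.end, r.region_class) for r in rebuilt} == {
            (r.chrom, r.start, r.end, r.region_class) for r in original
        }
        res = runner.invoke(
            cli_main,
            [
                "prioritize",
                "--arm", "de-novo",
                "--gff", str(out / "transcripts.gff3"),
                "--fasta", str(out / "genome.fa"),
                "--ccre", str(out / "ccres.bed"),
                "--variants", str(out / "variants.vcf"),
                "--tracks", str(out / "tracks.bed"),
                "--tf-predictions", str(out / "tf_predictions.tsv"),
                "--out", str(tmp_path / "decisions.tsv"),
            ],
        )
        assert res.exit_code == 0, res.output
        decisions = pd.read_csv(tmp_path / "decisions.tsv", sep="\t")
        import json

        truth = json.loads((out / "truth.json").read_text())
        want = {v for v, t in truth.items() if t["expected_retained"]["de_novo"]}
        got = set(decisions[decisions["retained"]]["variant_id"])
        assert got == want

    def test_burden_cli(self, tmp_path):
        runner = CliRunner()
        spec = FixtureSpec(
            seed=9, cohort=CohortSpec(n_cases=120, n_controls=120, related_pairs=2)
        )
        t = simulate_cohort(spec)
        t.participants.to_csv(tmp_path / "participants.tsv", sep="\t", index=False)
        t.king_pairs.to_csv(tmp_path / "king.tsv", sep="\t", index=False)
        carriers = t.carriers[t.carriers["carrier"]].copy()
        carriers["annotation_label"] = "all"
        carriers[["participant_id", "annotation_label"]].to_csv(
            tmp_path / "carriers.tsv", sep="\t", index=False
        )
        res = runner.invoke(
            cli_main,
            [
                "burden",
                "--cohort", str(tmp_path / "participants.tsv"),
                "--king", str(tmp_path / "king.tsv"),
                "--carriers", str(tmp_path / "carriers.tsv"),
                "--min-stratum-n", "0",
                "--seed", "1",
                "--out", str(tmp_path / "burden.tsv"),
            ],
        )
        assert res.exit_code == 0, res.output
        results = pd.read_csv(tmp_path / "burden.tsv", sep="\t")
        assert len(results) == 1
        assert 0.0 <= results.loc[0, "p_value"] <= 1.0
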