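"""Nesting, nearest-TE assignment, orientation and metaprofile construction
checked against exhaustive oracles and generator ground truth."""

import numpy as np
import pandas as pd
import pytest

from temethyl import profiles as pr
from temethyl import synthetic as syn
from temethyl import tiles as tl
from temethyl.config import ProfileConfig


def _te(chrom, start, end, id, family="f", order="LTR", superfamily="RLG",
        nested=False, **kw):
    return dict(chrom=chrom, start=start, end=end, id=id, strand="+",
                order=order, superfamily=superfamily, family=family,
                nested=nested, **kw)


class TestFlagNested:
    def test_containment(self):
        tes = pd.DataFrame([_te("chr1", 50, 900, "outer"),
                            _te("chr1", 100, 500, "inner")])
        out = pr.flag_nested(tes).set_index("id")["nested"]
        assert not out["outer"] and out["inner"]

    def test_partial_overlap_not_nested(self):
        tes = pd.DataFrame([_te("chr1", 100, 500, "a"),
                            _te("chr1", 400, 900, "b")])
        out = pr.flag_nested(tes)
        assert not out["nested"].any()

    def test_identical_intervals_tie_break(self):
        tes = pd.DataFrame([_te("chr1", 100, 500, "aa"),
                            _te("chr1", 100, 500, "b")])
        out = pr.flag_nested(tes).set_index("id")["nested"]
        # exactly one stays outer, deterministically
        assert out.sum() == 1
        assert out["b"]  # shorter id flagged

    def test_matches_brute_force_on_random_intervals(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 10_000, 200)
        lens = rng.integers(50, 2000, 200)
        tes = pd.DataFrame([
            _te("chr1", int(s), int(s + l), f"te{i:03d}")
            for i, (s, l) in enumerate(zip(starts, lens))
        ])
        out = pr.flag_nested(tes).set_index("id")["nested"]
        for i in tes.itertuples():
            expected = any(
                (j.start <= i.start and i.end <= j.end and j.id != i.id
                 and (j.start, j.end) != (i.start, i.end))
                for j in tes.itertuples()
            )
            dup_outer = any(
                (j.start, j.end) == (i.start, i.end) and j.id != i.id
                and sorted([j.id, i.id], key=lambda x: (len(x), x))[-1] == j.id
                for j in tes.itertuples()
            )
            assert out[i.id] == (expected or dup_outer), i.id


def _empty_tiles(chrom_len, chrom="chr1"):
    return tl.tile_methylome(pd.DataFrame(columns=[
        "chrom", "pos", "strand", "context", "mc_count", "total_count"
    ]), {chrom: chrom_len})


class TestAssignFlankTiles:
    def test_nearest_by_gap(self):
        tes = pd.DataFrame([_te("chr1", 700, 900, "a"),
                            _te("chr1", 1400, 1600, "b")])
        tiles = _empty_tiles(2000)
        out = pr.assign_flank_tiles(tiles, tes)
        row = out[out["start"] == 1000].iloc[0]
        assert row["te_id"] == "a" and row["distance"] == 100
        assert row["side"] == "right"

    def test_tiles_in_te_bodies_excluded(self):
        tes = pd.DataFrame([_te("chr1", 700, 950, "a")])
        tiles = _empty_tiles(2000)
        out = pr.assign_flank_tiles(tiles, tes)
        assert not set(out["start"]) & {700, 800, 900}

    def test_equidistant_tie_goes_to_smaller_start(self):
        tes = pd.DataFrame([_te("chr1", 500, 700, "a"),
                            _te("chr1", 1300, 1500, "b")])
        tiles = _empty_tiles(2000)
        out = pr.assign_flank_tiles(tiles, tes)
        # tile [950,1050) doesn't exist on the grid; use [900,1000):
        # gap to a = 200, gap to b = 300 -> a; the true tie is [1000,1100)
        # gap a = 300, gap b = 200 -> b.  Construct an exact tie instead:
        tes2 = pd.DataFrame([_te("chr1", 500, 700, "a"),
                             _te("chr1", 1400, 1600, "b")])
        out2 = pr.assign_flank_tiles(tiles, tes2)
        row = out2[out2["start"] == 1000].iloc[0]
        assert row["distance"] == 300 and row["te_id"] == "a"

    def test_matches_quadratic_oracle(self):
        """200 random TEs / 1000 tiles: nearest assignment equals brute force
        and no flank tile overlaps any TE body."""
        rng = np.random.default_rng(1)
        starts = np.sort(rng.choice(np.arange(0, 99_000), 200, replace=False))
        tes = pd.DataFrame([
            _te("chr1", int(s), int(s + rng.integers(80, 800)), f"te{i:03d}")
            for i, s in enumerate(starts)
        ])
        tes = pr.flag_nested(tes)
        tiles = _empty_tiles(100_000)
        out = pr.assign_flank_tiles(tiles, tes, ProfileConfig())
        cand = tes[~tes["nested"]].sort_values("start")
        assigned = out.set_index("start")
        for t in tiles.itertuples():
            gaps = np.maximum(
                np.maximum(cand["start"] - t.end, t.start - cand["end"]), 0
            )
            body_overlap = (
                (tes["start"] < t.end) & (t.start < tes["end"])
            ).any()
            if body_overlap or gaps.min() >= 1000:
                assert t.start not in assigned.index
                continue
            best = cand.iloc[int(np.argmin(gaps.to_numpy()))]
            row = assigned.loc[t.start]
            assert row["te_id"] == best["id"]
            assert row["distance"] == int(gaps.min())
            # flank tile never overlaps the assigned TE body
            te = tes.set_index("id").loc[row["te_id"]]
            assert t.end <= te["start"] or t.start >= te["end"]


class TestOrientation:
    def _tiles_with_cg(self, values):
        tiles = _empty_tiles(4000)
        tiles["cg_ratio"] = np.nan
        for start, v in values.items():
            tiles.loc[tiles["start"] == start, "cg_ratio"] = v
        tiles["chg_ratio"] = tiles["cg_ratio"]
        return tiles

    def test_higher_upstream_keeps_orientation(self):
        tes = pd.DataFrame([_te("chr1", 1500, 2500, "a")])
        tiles = self._tiles_with_cg({1400: 0.8, 2500: 0.3})
        profs = pr.element_profiles(tiles, tes, ["cg_ratio"],
                                    ProfileConfig())
        mat = profs["a"]
        assert np.nanmean(mat[:10, 0]) >= np.nanmean(mat[20:, 0])
        assert mat[9, 0] == pytest.approx(0.8)

    def test_higher_downstream_flips(self):
        tes = pd.DataFrame([_te("chr1", 1500, 2500, "a")])
        tiles = self._tiles_with_cg({1400: 0.3, 2500: 0.8})
        mat = pr.element_profiles(tiles, tes, ["cg_ratio"],
                                  ProfileConfig())["a"]
        assert mat[9, 0] == pytest.approx(0.8)  # high flank now on the left

    def test_exact_tie_keeps_genomic(self):
        tes = pd.DataFrame([_te("chr1", 1500, 2500, "a")])
        tiles = self._tiles_with_cg(
            {1300: 0.1, 1400: 0.9, 2500: 0.5, 2600: 0.5}
        )
        mat = pr.element_profiles(tiles, tes, ["cg_ratio"],
                                  ProfileConfig())["a"]
        # flank means tie at 0.5; genomic orientation kept, so the upstream
        # bin at gap 100-200 bp keeps its 0.1
        assert mat[8, 0] == pytest.approx(0.1)

    def test_orientation_invariant_after_orientation(self, archetype_dataset):
        """Left-flank mean CG >= right-flank mean CG for every element, and
        re-orienting an oriented profile changes nothing."""
        tes = pr.flag_nested(archetype_dataset["tes"])
        profs = pr.element_profiles(
            archetype_dataset["tiles"], tes, ["cg_ratio"], ProfileConfig()
        )
        cfg = ProfileConfig()
        for te_id, mat in profs.items():
            left = np.nanmean(mat[:10, 0])
            right = np.nanmean(mat[20:, 0])
            if np.isnan(left) or np.isnan(right):
                continue
            assert left >= right - 1e-12, te_id
            assert not pr.orient_matrix_needed(mat, ["cg_ratio"], cfg)


class TestFamilyProfiles:
    def test_constant_signal_gives_constant_profile(self):
        tes = pd.DataFrame([
            _te("chr1", 1500 + i * 4000, 2500 + i * 4000, f"m{i}")
            for i in range(3)
        ])
        tiles = _empty_tiles(16_000)
        tiles["cg_ratio"] = 0.8
        tiles["chg_ratio"] = 0.8
        prof = pr.family_profiles(
            tiles, tes, ["cg_ratio"], ProfileConfig(min_members=3)
        )
        assert np.allclose(prof["mean"].dropna(), 0.8)

    def test_member_order_invariance(self, archetype_dataset):
        tes = pr.flag_nested(archetype_dataset["tes"])
        cfg = ProfileConfig(min_members=5)
        a = pr.family_profiles(archetype_dataset["tiles"], tes, config=cfg)
        shuffled = tes.sample(frac=1.0, random_state=0).reset_index(drop=True)
        b = pr.family_profiles(archetype_dataset["tiles"], shuffled, config=cfg)
        key = ["family", "bin", "signal"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )

    def test_small_family_excluded(self, archetype_dataset):
        tes = pr.flag_nested(archetype_dataset["tes"])
        prof = pr.family_profiles(
            archetype_dataset["tiles"], tes,
            config=ProfileConfig(min_members=20),
        )
        assert len(prof) == 0  # all families have 10 members

    def test_decay_length_recovered_from_archetype_L(self):
        """Fitting the flank decay of a low-flank family recovers the
        generator's decay length within 20%."""
        fams = [syn.TEFamilyConfig(name="famL", superfamily="RLG",
                                   n_members=25)]
        genome, _, tes = syn.generate_reference(
            syn.GenomeSpec(chrom_len=400_000, n_genes=0, seed=9), fams
        )
        arch = syn.DEFAULT_ARCHETYPES["L"]
        calls = syn.simulate_methylome(genome, tes, {"famL": arch},
                                       depth=30, seed=10)
        tiles = tl.tile_methylome(calls, {c: len(s) for c, s in genome.items()})
        prof = pr.family_profiles(tiles, pr.flag_nested(tes),
                                  config=ProfileConfig(min_members=20))
        cg = prof[(prof["signal"] == "cg_ratio")
                  & (prof["bin"] < 10)].sort_values("bin")
        # per-bin closed-form mean distances: bin 9 nearest (1-100bp)
        d = np.array([(9 - b) * 100 + 50.5 for b in cg["bin"]])
        y = cg["mean"].to_numpy()
        # fit decay by least squares on log-transformed excess methylation
        excess = np.clip(y - arch.flank_plateau, 1e-3, None)
        mask = excess > 0.02
        slope = np.polyfit(d[mask], np.log(excess[mask]), 1)[0]
        fitted = -1 / slope
        assert fitted == pytest.approx(arch.decay_length, rel=0.20)


class TestGroupProfiles:
    def test_cpm_normalization_identity(self):
        counts = pd.DataFrame(dict(
            chrom="chr1", start=[0, 100, 200], end=[100, 200, 300],
            count=[2, 0, 8],
        ))
        out = pr.window_cpm(counts)
        assert out["cpm"].tolist() == [2e5, 0.0, 8e5]
        assert out["cpm"].sum() == pytest.approx(1e6)

    def test_zero_total_rejected(self):
        counts = pd.DataFrame(dict(chrom="chr1", start=[0], end=[100],
                                   count=[0]))
        with pytest.raises(ValueError):
            pr.window_cpm(counts)

    def test_short_tirs_excluded(self, caplog):
        tes = pd.DataFrame([
            _te("chr1", 1000, 1500, "t1", order="TIR", superfamily="DTA",
                group="L"),
        ])
        tiles = _empty_tiles(3000)
        tiles["cpm"] = 1.0
        import logging

        with caplog.at_level(logging.WARNING, logger="temethyl.profiles"):
            out = pr.group_profiles(tiles, tes, ["cpm"])
        assert len(out) == 0
        assert "no elements" in caplog.text

    def test_group_mean_is_convex_combination(self, archetype_dataset):
        """Every group-profile bin lies within [min, max] of member values."""
        tes = pr.flag_nested(archetype_dataset["tes"]).assign(
            group=lambda d: d["family"].str[-1]
        )
        tiles = archetype_dataset["tiles"]
        profs = pr.element_profiles(tiles, tes, ["cg_ratio"], ProfileConfig())
        out = pr.group_profiles(tiles, tes, ["cg_ratio"], tir_min_len=0)
        for (group, b), sub in out.groupby(["group", "bin"]):
            members = tes[tes["group"] == group]["id"]
            vals = np.array([profs[m][b, 0] for m in members])
            if np.all(np.isnan(vals)):
                continue
            m = sub["mean"].iloc[0]
            assert np.nanmin(vals) - 1e-9 <= m <= np.nanmax(vals) + 1e-9

    def test_doubled_flank_cpm_recovered(self):
        """Group with doubled flank chromatin intensity shows flank/body
        CPM ratio of ~2 in its profile."""
        tes = pd.DataFrame([
            _te("chr1", 5000 + i * 14_000, 7000 + i * 14_000, f"m{i}",
                group="L")
            for i in range(10)
        ])
        sizes = {"chr1": 150_000}
        counts = syn.simulate_chromatin_counts(
            sizes, tes, 3_000_000,
            group_profiles={"L": {"body": 1.0, "flank": 2.0}},
            group_col="group", seed=2,
        )
        cpm = pr.window_cpm(counts)
        tiles = _empty_tiles(150_000).merge(
            cpm[["chrom", "start", "cpm"]], on=["chrom", "start"]
        )
        out = pr.group_profiles(tiles, tes, ["cpm"], tir_min_len=0)
        flank = out[out["bin"].isin(range(10))]["mean"].mean()
        body = out[out["bin"].isin(range(10, 20))]["mean"].mean()
        assert flank / body == pytest.approx(2.0, rel=0.1)


class TestAttributes:
    def test_gene_distance_bins(self):
        tes = pd.DataFrame([
            _te("chr1", 900, 1500, "overlap", group="H"),
            _te("chr1", 2500, 2900, "near", group="H"),
            _te("chr1", 8000, 8400, "mid", group="H"),
            _te("chr1", 50_000, 50_400, "far", group="H"),
        ])
        genes = pd.DataFrame([dict(chrom="chr1", start=1000, end=2000,
                                   id="g1", strand="+")])
        out = pr.distance_to_gene(tes, genes).set_index("te_id")
        assert out.loc["overlap", "overlapping"]
        assert out.loc["overlap", "distance"] == 0
        assert out.loc["near", "distance"] == 500
        assert pr._gene_distance_bin(500, False) == "<1kb"
        assert pr._gene_distance_bin(4000, False) == "1-5kb"
        assert pr._gene_distance_bin(48_000, False) == ">5kb"

    def test_closest_gene_tie_break(self):
        tes = pd.DataFrame([_te("chr1", 2000, 2400, "t", group="H")])
        genes = pd.DataFrame([
            dict(chrom="chr1", start=1500, end=1900, id="gA", strand="+"),
            dict(chrom="chr1", start=2500, end=2900, id="gB", strand="+"),
        ])
        out = pr.distance_to_gene(tes, genes)
        assert out.iloc[0]["gene_id"] == "gA"  # equal gap 100, smaller start

    def test_family_size_bin(self):
        assert pr._family_size_bin(120) == "100-200"
        assert pr._family_size_bin(20) == "20-50"
        assert pr._family_size_bin(250) == ">200"

    def test_expression_flag_and_proportions(self):
        tes = pd.DataFrame([
            _te("chr1", 1000 + i * 3000, 1400 + i * 3000, f"t{i}",
                family=f"fam{i % 2}", group="H" if i < 4 else "L")
            for i in range(8)
        ])
        genes = pd.DataFrame([dict(chrom="chr1", start=100, end=500,
                                   id="g", strand="+")])
        rpm = pd.DataFrame(
            dict(family=["fam0", "fam1"], root=[0.2, 0.0],
                 shoot=[1.5, 0.9], leaf=[0.0, 0.3])
        )
        out = pr.attribute_summary(tes, genes, rpm_table=rpm)
        expr = out["expression"].set_index("group")["prop_expressed"]
        # fam0 expressed (1.5 > 1), fam1 not; both groups contain both fams
        assert expr["H"] == pytest.approx(0.5)
        for facet in ("superfamily", "gene_distance", "family_size"):
            sums = out[facet].groupby("group")["proportion"].sum()
            assert np.allclose(sums, 1.0, atol=1e-9)

    def test_cytosine_density_flanks_vs_body(self, archetype_dataset):
        tes = pr.flag_nested(archetype_dataset["tes"]).assign(
            group=lambda d: d["family"].str[-1]
        )
        out = pr.cytosine_density(archetype_dataset["genome"], tes)
        assert set(out["context"]) == {"CG", "CHG", "CHH"}
        assert (out["sites_per_100bp"].dropna() > 0).all()
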