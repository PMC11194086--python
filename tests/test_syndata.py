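"""Generator contracts: determinism, planted fractions, truth consistency."""

import numpy as np
import pandas as pd
import pytest
import scipy.io

from senoscore import qc, syndata
from senoscore.syndata import (
    ConfigurationError,
    GenerationError,
    IntensityConfig,
    LandscapeConfig,
    SimConfig,
    generate_cell_population,
    generate_intensity_table,
    generate_regulatory_landscape,
    write_fixtures,
)


def _small_cfg(**kw):
    base = dict(
        seed=1,
        n_cells=400,
        n_genes=300,
        module_sizes={"maturation": 30, "isg": 15, "sasp": 10},
        module_loadings={"maturation": 0.9, "isg": 0.6, "sasp": 0.0},
    )
    base.update(kw)
    return SimConfig(**base)


class TestCellPopulation:
    def test_same_seed_identical_counts(self):
        a = generate_cell_population(_small_cfg())
        b = generate_cell_population(_small_cfg())
        assert (a.counts != b.counts).nnz == 0
        pd.testing.assert_frame_equal(a.cell_meta, b.cell_meta)

    def test_column_sums_equal_library_size(self, small_population):
        totals = np.asarray(small_population.counts.sum(axis=0)).ravel()
        assert np.array_equal(totals, small_population.cell_meta["library_size"].to_numpy())

    def test_marker_flagged_once_and_modules_partition(self, small_population):
        gm = small_population.gene_meta
        assert gm["is_marker"].sum() == 1
        sizes = gm[gm["module"] != ""]["module"].value_counts().to_dict()
        assert sizes == small_population.config.module_sizes

    def test_marker_detection_tracks_planted_fraction(self):
        cfg = _small_cfg(seed=3, n_cells=2000, frac_senescent=0.15, marker_capture=1.0)
        pop = generate_cell_population(cfg)
        cm = qc.CountMatrix.from_population(pop)
        frac = qc.detected_fraction(cm, cfg.marker_gene)
        # binomial noise around the planted fraction (Poisson detection is
        # near-complete for the marker's senescent-cell mean)
        se = np.sqrt(0.15 * 0.85 / cfg.n_cells)
        assert abs(frac - 0.15) < 4 * se + 0.01

    def test_zero_loadings_give_null_marker_correlations(self, null_population):
        pop = null_population
        lam = pop.counts.toarray() / pop.cell_meta["library_size"].to_numpy()
        mrow = int(np.flatnonzero(pop.gene_meta["is_marker"].to_numpy())[0])
        module_rows = np.flatnonzero((pop.gene_meta["module"] != "").to_numpy())
        r = np.array([np.corrcoef(lam[g], lam[mrow])[0, 1] for g in module_rows])
        assert abs(np.nanmean(r)) < 3.0 / np.sqrt(pop.counts.shape[1])

    def test_planted_signal_monotone_in_loading(self):
        med = []
        for loading in (0.2, 0.6, 1.2):
            cfg = _small_cfg(
                seed=5,
                n_cells=800,
                module_loadings={"maturation": loading, "isg": 0.0, "sasp": 0.0},
            )
            pop = generate_cell_population(cfg)
            lam = pop.counts.toarray() / pop.cell_meta["library_size"].to_numpy()
            sen = pop.cell_truth["senescent"].to_numpy().astype(float)
            rows = np.flatnonzero((pop.gene_meta["module"] == "maturation").to_numpy())
            r = [np.corrcoef(lam[g], sen)[0, 1] for g in rows]
            med.append(np.median(r))
        assert med[0] < med[1] < med[2]

    def test_oversized_modules_rejected(self):
        with pytest.raises(ConfigurationError):
            _small_cfg(module_sizes={"maturation": 500, "isg": 15, "sasp": 10}).validate()

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            _small_cfg(frac_senescent=1.5).validate()


class TestLandscape:
    def test_planted_promoters_carry_all_three_marks(self, small_landscape):
        land = small_landscape
        prom_sites = land.ctcf_truth[land.ctcf_truth["category"] == "promoter"]
        tss = land.tss_table.set_index("gene")
        for gene in prom_sites["linked_gene"]:
            t = tss.loc[gene, "tss"]
            for mark in ("H3K27ac", "ATAC", "H3K4me3"):
                peaks = land.peaks[mark]
                hit = ((peaks["start"] < t + 2000) & (peaks["end"] > t - 2000)).any()
                assert hit, f"{mark} missing around TSS of {gene}"

    def test_intervals_inside_chromosome(self, small_landscape):
        size = small_landscape.chrom_sizes[small_landscape.config.chrom]
        for df in [*small_landscape.peaks.values(), small_landscape.tad_boundaries,
                   small_landscape.ctcf_sites]:
            assert (df["start"] >= 0).all() and (df["end"] <= size).all()
            assert (df["start"] < df["end"]).all()

    def test_null_region_count_ratio_tracks_depth(self, small_landscape):
        land = small_landscape
        null = land.region_truth[land.region_truth["planted_log2fc"] == 0].index
        counts = land.region_counts.loc[null]
        col_tot = counts.sum(axis=0).to_numpy(float)
        ratio = col_tot / col_tot.mean()
        assert ratio.std() < 0.5  # depths are lognormal(0, 0.15)

    def test_coupling_fraction(self):
        land = generate_regulatory_landscape(
            LandscapeConfig(seed=11, n_boundary_sites=100, coupling=0.9)
        )
        bl = land.ctcf_truth[
            (land.ctcf_truth["category"] == "tad_boundary")
            & (land.ctcf_truth["planted_log2fc"] < 0)
        ]
        up = land.gene_truth.loc[bl["linked_gene"], "upregulated"].mean()
        assert abs(up - 0.9) < 4 * np.sqrt(0.9 * 0.1 / len(bl))

    def test_infeasible_packing_raises(self):
        with pytest.raises(GenerationError):
            LandscapeConfig(chrom_length=1_000_000).validate()


class TestIntensity:
    def test_determinism_and_positivity(self):
        a = generate_intensity_table(IntensityConfig(seed=2))
        b = generate_intensity_table(IntensityConfig(seed=2))
        pd.testing.assert_frame_equal(a, b)
        assert (a["p16"] > 0).all() and (a["foci_count"] >= 0).all()

    def test_foci_rate_ratio(self):
        cfg = IntensityConfig(seed=4, n_cells=20000, foci_rates=(0.15, 0.30))
        t = generate_intensity_table(cfg)
        sen = t[t["senescent_truth"] == 1]["foci_count"].mean()
        non = t[t["senescent_truth"] == 0]["foci_count"].mean()
        assert abs(sen / non - 2.0) < 0.35

    def test_zero_shift_gives_chance_classification(self):
        cfg = IntensityConfig(seed=6, n_cells=5000,
                              channels={"p16": (4.0, 0.0, 0.5)})
        t = generate_intensity_table(cfg)
        top = t["p16"] > t["p16"].quantile(0.8)
        enrich = t.loc[top, "senescent_truth"].mean()
        assert abs(enrich - cfg.frac_senescent) < 0.05

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ConfigurationError):
            IntensityConfig(foci_rates=(0.0, 0.3)).validate()


class TestFixtures:
    def test_round_trip_and_manifest(self, tmp_path, small_landscape):
        pop = generate_cell_population(_small_cfg(seed=8, n_cells=80, n_genes=120,
            module_sizes={"maturation": 10, "isg": 5, "sasp": 5}))
        table = generate_intensity_table(IntensityConfig(seed=8, n_cells=50))
        manifest = write_fixtures(pop, small_landscape, table, tmp_path)
        back = scipy.io.mmread(tmp_path / "counts.mtx").tocsr()
        assert (back != pop.counts).nnz == 0
        bed = pd.read_csv(tmp_path / "peaks_H3K27ac.bed", sep="\t", header=None)
        assert bed[1].is_monotonic_increasing  # single toy chromosome
        # checksum changes iff a file changes
        manifest2 = write_fixtures(pop, small_landscape, table, tmp_path)
        assert manifest == manifest2
        (tmp_path / "tss.tsv").write_text("gene\tchrom\ttss\tstrand\n")
        from senoscore.io import sha256_file
        assert sha256_file(tmp_path / "tss.tsv") != manifest["tss.tsv"]
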