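"""Generator contracts: composition summaries, dictionaries, planted truth."""

import numpy as np
import pandas as pd
import pytest

from crcpathways import syndata
from crcpathways.syndata import (
    PlantedPathway,
    SimulationDesign,
    generate_pathway_dictionary,
    probe_annotation,
    reference_composition_table,
    simulate_experiment,
    summarize_cell_composition,
)


class TestCellComposition:
    @pytest.mark.parametrize(
        "column, total, pct",
        [
            ("Normal colon", 4456, 71.4),
            ("Normal colon from tumor", 4791, 63.3),
            ("Adenoma", 3087, 53.4),
            ("Carcinoma", 2863, 81.4),
        ],
    )
    def test_reference_table_worked_examples(self, column, total, pct):
        summary = summarize_cell_composition(reference_composition_table())
        assert summary.loc[column, "total"] == total
        assert summary.loc[column, "epithelial_percent"] == pct

    def test_single_row_column_is_all_epithelial(self):
        table = pd.DataFrame({"only": [7]}, index=["Epithelial cells"])
        summary = summarize_cell_composition(table)
        assert summary.loc["only", "total"] == 7
        assert summary.loc["only", "epithelial_percent"] == 100.0

    def test_half_up_rounding(self):
        # 1/8 = 12.5% must round up to 12.5 -> 12.5; 5/16 = 31.25 -> 31.3
        table = pd.DataFrame({"c": [5, 11]}, index=["Epithelial cells", "Other"])
        assert (
            summarize_cell_composition(table).loc["c", "epithelial_percent"] == 31.3
        )

    def test_zero_total_rejected(self):
        table = pd.DataFrame({"c": [0, 0]}, index=["Epithelial cells", "Other"])
        with pytest.raises(ValueError, match="zero total"):
            summarize_cell_composition(table)

    def test_missing_epithelial_row_rejected(self):
        table = pd.DataFrame({"c": [3]}, index=["Fibroblasts"])
        with pytest.raises(ValueError, match="epithelial row"):
            summarize_cell_composition(table)


class TestPathwayDictionary:
    def test_kegg_scale_generation(self):
        universe = [f"G{i:05d}" for i in range(30000)]
        sets = generate_pathway_dictionary(200, (10, 150), universe, seed=3)
        assert len(sets) == 200
        sizes = [len(v) for v in sets.values()]
        assert min(sizes) >= 10 and max(sizes) <= 150
        for members in sets.values():
            assert len(set(members)) == len(members)
            assert set(members) <= set(universe)

    def test_forced_single_set_equals_universe(self):
        universe = ["a", "b", "c", "d", "e"]
        sets = generate_pathway_dictionary(1, (5, 5), universe, seed=0)
        (members,) = sets.values()
        assert sorted(members) == sorted(universe)

    def test_deterministic_under_seed(self, tmp_path):
        from crcpathways.io import write_gmt

        universe = [f"G{i}" for i in range(500)]
        paths = []
        for run in range(2):
            sets = generate_pathway_dictionary(30, (5, 25), universe, seed=42)
            p = tmp_path / f"run{run}.gmt"
            write_gmt(sets, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            generate_pathway_dictionary(5, (2, 3), [], seed=0)

    def test_oversized_range_rejected(self):
        with pytest.raises(ValueError, match="exceeds universe"):
            generate_pathway_dictionary(5, (2, 10), ["a", "b"], seed=0)


class TestSimulateExperiment:
    def test_shapes_and_annotation(self, small_design, small_experiment):
        matrix, samples, truth = small_experiment
        assert matrix.shape == (400, 30)
        assert set(samples["group"]) == {"NC", "AD", "CA"}
        assert set(samples["sex"]) <= {"M", "F"}
        assert (matrix.to_numpy() > 0).all()

    def test_determinism(self, small_design, small_dictionary):
        m1, s1, t1 = simulate_experiment(small_design, small_dictionary)
        m2, s2, t2 = simulate_experiment(small_design, small_dictionary)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(s1, s2)
        assert t1.to_dict() == t2.to_dict()

    def test_ground_truth_closure(self, small_experiment):
        matrix, _, truth = small_experiment
        probes = set(matrix.index)
        for ids in truth.de_probe_ids.values():
            assert set(ids) <= probes
        assert set(truth.monotone_up_ids) <= probes
        assert set(truth.monotone_down_ids) <= probes
        assert not set(truth.monotone_up_ids) & set(truth.monotone_down_ids)

    def test_y_probes_near_background_in_females(self, small_design, small_experiment):
        matrix, samples, _ = small_experiment
        annot = probe_annotation(small_design)
        y = annot.index[annot["is_chrY"] == 1]
        females = samples.index[samples["sex"] == "F"]
        males = samples.index[samples["sex"] == "M"]
        log2 = np.log2(matrix + 1.0)
        assert log2.loc[y, females].to_numpy().mean() < small_design.background_log2 + 1.5
        assert log2.loc[y, males].to_numpy().mean() > small_design.background_log2 + 2.0

    def test_monotone_groups_strictly_ordered(self, small_design, small_experiment):
        matrix, samples, truth = small_experiment
        log2 = np.log2(matrix + 1.0)
        means = log2.loc[truth.monotone_up_ids].T.groupby(samples["group"].values).mean().T
        assert ((means["NC"] < means["AD"]) & (means["AD"] < means["CA"])).mean() > 0.9
        means_dn = (
            log2.loc[truth.monotone_down_ids].T.groupby(samples["group"].values).mean().T
        )
        assert ((means_dn["NC"] > means_dn["AD"]) & (means_dn["AD"] > means_dn["CA"])).mean() > 0.9

    def test_planted_pathway_absent_from_dictionary_rejected(self, small_dictionary):
        design = SimulationDesign(
            n_probes=100,
            n_samples_per_group={"NC": 3, "AD": 3, "CA": 3},
            planted_pathways=(PlantedPathway("NOPE", "NC_vs_AD+CA", 1.0),),
            n_monotone_up=0,
            n_monotone_down=0,
            y_probe_count=5,
            seed=1,
        )
        with pytest.raises(ValueError, match="absent from dictionary"):
            simulate_experiment(design, small_dictionary)

    def test_epithelium_affinity_planted(self, small_design, small_dictionary):
        matrix, samples, truth = simulate_experiment(small_design, small_dictionary)
        annot = probe_annotation(small_design)
        genes = set(small_dictionary["PW002"])
        members = annot.index[annot["gene_symbol"].isin(genes)]
        log2 = np.log2(matrix + 1.0)
        epi = pd.Series(truth.epithelium_fraction)
        corr = log2.loc[members].T.corrwith(epi)
        assert corr.mean() > 0.2  # members track the epithelium axis
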