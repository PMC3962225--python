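"""Compound Series Matrix construction, statistics, and virtual compounds."""

import pytest
from rdkit import Chem

from promispace.csm import (
    CSMCell,
    CompoundSeriesMatrix,
    build_csms,
    build_series,
    csm_statistics,
    design_candidates,
    extract_promiscuous_submatrix,
    read_csm_json,
    write_csm_json,
)
from promispace.errors import EmptySubmatrixError, MalformedInputError
from promispace.fixtures import FixtureSpec, generate_analog_grid

PHENYL = "c1ccc([*:1])cc1"
PARA_F = "Fc1ccc([*:1])cc1"
ME, OME, IPR = "C[*:1]", "CO[*:1]", "CC(C)[*:1]"


class TestBuildSeries:
    def test_toluene_ethylbenzene_series(self):
        series = build_series({"tol": "Cc1ccccc1", "eb": "CCc1ccccc1"})
        (s,) = series
        assert s.core == PHENYL
        assert dict(s.members) == {ME: "tol", "CC[*:1]": "eb"}

    def test_no_mmps_means_no_series(self):
        assert build_series({"a": "c1ccccc1", "b": "C1CCCCC1"}) == []

    def test_planted_three_series(self):
        ds, gt = generate_analog_grid(
            FixtureSpec(families=("thiophene",), substituents=("[*:1]C", "[*:1]OC", "[*:1]C#N"), deletion_fraction=0.0, seed=1)
        )
        series = build_series(ds)
        assert len(series) == 3
        assert {s.core: dict(s.members) for s in series} == gt.series


class TestBuildCsms:
    @pytest.fixture
    def four_compound_csm(self):
        structures = {
            "tol": "Cc1ccccc1",        # phenyl + Me
            "anis": "COc1ccccc1",      # phenyl + OMe
            "ftol": "Cc1ccc(F)cc1",    # para-F-phenyl + Me
            "fcum": "CC(C)c1ccc(F)cc1" # para-F-phenyl + iPr
        }
        return build_csms(build_series(structures))

    def test_two_by_three_layout(self, four_compound_csm):
        (m,) = four_compound_csm
        assert m.rows == [PHENYL, PARA_F]
        assert m.columns == [ME, OME, IPR]
        assert len(m.real_cells) == 4
        assert m.virtual_cells == {(PHENYL, IPR), (PARA_F, OME)}

    def test_grid_tiling_invariant(self, four_compound_csm):
        (m,) = four_compound_csm
        assert len(m.real_cells) + len(m.virtual_cells) == len(m.rows) * len(m.columns)

    def test_unrelated_single_cores_produce_no_csm(self):
        structures = {
            "tol": "Cc1ccccc1",
            "anis": "COc1ccccc1",
            "mcy": "CC1CCCCC1",
            "ocy": "COC1CCCCC1",
        }
        series = build_series(structures)
        assert len(series) == 2  # phenyl and cyclohexyl series
        assert build_csms(series) == []

    def test_real_cells_reassemble_to_their_compounds(self):
        ds, gt = generate_analog_grid(FixtureSpec(seed=5))
        csms = build_csms(build_series(ds), target_sets=gt.target_sets)
        from promispace.fragmentation import reassemble

        for m in csms:
            for (core, sub), cell in m.real_cells.items():
                assert reassemble(core, sub) == Chem.CanonSmiles(
                    gt.compounds[cell.compound_id]
                )

    def test_target_counts_attached(self):
        structures = {"tol": "Cc1ccccc1", "anis": "COc1ccccc1", "ftol": "Cc1ccc(F)cc1", "fcum": "CC(C)c1ccc(F)cc1"}
        target_sets = {"tol": {"T1", "T2"}, "anis": {"T1"}, "ftol": set(), "fcum": {"T3"}}
        (m,) = build_csms(build_series(structures), target_sets=target_sets)
        assert m.cells[(PHENYL, ME)].target_count == 2
        assert m.cells[(PARA_F, ME)].target_count == 0


class TestCsmStatistics:
    def _matrix(self, target_sets):
        structures = {
            "tol": "Cc1ccccc1",
            "anis": "COc1ccccc1",
            "ftol": "Cc1ccc(F)cc1",
            "fanis": "COc1ccc(F)cc1",
        }
        return build_csms(build_series(structures), target_sets=target_sets)

    def test_all_single_target_is_not_multi_target(self):
        csms = self._matrix({"tol": {"T1"}, "anis": {"T2"}, "ftol": {"T1"}, "fanis": {"T2"}})
        stats = csm_statistics(csms, {"T1": "GPCR-A", "T2": "GPCR-A"})
        assert stats.n_csms == 1
        assert stats.n_multi_target_csms == 0

    def test_family_span_classification(self):
        csms = self._matrix({"tol": {"T1", "T2"}, "anis": {"T3"}, "ftol": set(), "fanis": set()})
        stats = csm_statistics(csms, {"T1": "GPCR-A", "T2": "kinase", "T3": "GPCR-A"})
        assert stats.n_multi_target_csms == 1
        assert stats.n_multi_family == 1
        assert stats.family_span_histogram == {2: 1}

    def test_partition_identity(self):
        ds, gt = generate_analog_grid(FixtureSpec(seed=2))
        csms = build_csms(build_series(ds), target_sets=gt.target_sets)
        stats = csm_statistics(csms, gt.target_families)
        assert stats.n_single_family + stats.n_multi_family == stats.n_multi_target_csms
        assert sum(stats.family_span_histogram.values()) == stats.n_multi_target_csms


class TestSubmatrixExtraction:
    @pytest.fixture
    def csm(self):
        structures = {"tol": "Cc1ccccc1", "anis": "COc1ccccc1", "ftol": "Cc1ccc(F)cc1", "fcum": "CC(C)c1ccc(F)cc1"}
        target_sets = {"tol": {f"T{i}" for i in range(12)}, "anis": {"T1"}, "ftol": {"T1"}, "fcum": {"T2"}}
        (m,) = build_csms(build_series(structures), target_sets=target_sets)
        return m

    def test_single_promiscuous_cell_gives_1x1(self, csm):
        sub = extract_promiscuous_submatrix(csm, 5)
        assert sub.rows == [PHENYL]
        assert sub.columns == [ME]
        assert len(sub.real_cells) == 1
        assert sub.virtual_cells == set()

    def test_threshold_one_is_identity_on_real_cells(self, csm):
        sub = extract_promiscuous_submatrix(csm, 1)
        assert sub.real_cells == csm.real_cells

    def test_empty_extraction_is_an_error(self, csm):
        with pytest.raises(EmptySubmatrixError):
            extract_promiscuous_submatrix(csm, 99)


class TestDesignCandidates:
    def test_hand_assembled_candidate(self):
        cells = {
            (PARA_F, "CC[*:1]"): CSMCell("virtual"),
            (PARA_F, ME): CSMCell("real", "ftol", 1, frozenset({"T1"})),
            (PHENYL, "CC[*:1]"): CSMCell("real", "eb", 1, frozenset({"T1"})),
            (PHENYL, ME): CSMCell("real", "tol", 1, frozenset({"T1"})),
        }
        m = CompoundSeriesMatrix([PHENYL, PARA_F], [ME, "CC[*:1]"], cells)
        (cand,) = design_candidates(m, "CC[*:1]")
        assert cand.smiles == Chem.CanonSmiles("CCc1ccc(F)cc1")
        assert cand.core == PARA_F

    def test_column_without_virtual_cells(self):
        structures = {"tol": "Cc1ccccc1", "anis": "COc1ccccc1", "ftol": "Cc1ccc(F)cc1", "fanis": "COc1ccc(F)cc1"}
        (m,) = build_csms(build_series(structures))
        assert design_candidates(m, ME) == []

    def test_unknown_column_is_an_error(self):
        m = CompoundSeriesMatrix([PHENYL], [ME], {(PHENYL, ME): CSMCell("real", "tol", 1, frozenset())})
        with pytest.raises(MalformedInputError):
            design_candidates(m, "CCC[*:1]")

    def test_all_planted_deletions_recovered(self):
        ds, gt = generate_analog_grid(FixtureSpec(seed=9))
        csms = build_csms(build_series(ds), target_sets=gt.target_sets)
        recovered = {
            (c.core, c.substituent): c.smiles
            for m in csms
            for col in m.columns
            for c in design_candidates(m, col)
        }
        expected = {
            coord: Chem.CanonSmiles(smi) for coord, smi in gt.deleted_smiles.items()
        }
        assert {k: Chem.CanonSmiles(v) for k, v in recovered.items()} == expected


def test_csm_json_round_trip(tmp_path):
    ds, gt = generate_analog_grid(FixtureSpec(seed=4))
    csms = build_csms(build_series(ds), target_sets=gt.target_sets)
    path = tmp_path / "csms.json"
    write_csm_json(csms, path)
    back = read_csm_json(path)
    assert len(back) == len(csms)
    for a, b in zip(back, csms):
        assert a.rows == b.rows and a.columns == b.columns and a.cells == b.cells
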