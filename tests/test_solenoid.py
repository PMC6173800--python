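"""Idealized beta-solenoid construction: geometry, stacking, sterics, PDB I/O."""

import io

import numpy as np
import pytest

import fapcore as fc
from fapcore.solenoid import BuildError

from conftest import make_segmentation


def ca_of(model, res, monomer=0):
    sel = (model.res_id == res) & (model.atom_name == "CA") & (model.monomer == monomer)
    return model.coords[sel][0]


class TestBuildSolenoid:
    def test_fapc_rung_atom_counts(self, fapc_model):
        # 3 x 37 residues, CA + CB each
        assert fapc_model.n_atoms == 2 * 111
        rung0 = [r for r, rr in fapc_model.rung_of.items() if rr == 0]
        assert len(rung0) == 37

    def test_strand_projected_length(self, fapc_model):
        # 14-residue strand: 13 gaps x 3.45 A along the strand axis
        xs = [ca_of(fapc_model, r)[0] for r in range(1, 15)]
        assert max(xs) - min(xs) == pytest.approx(13 * 3.45, abs=1e-6)

    def test_in_strand_ca_spacing(self, fapc_model):
        for res in range(1, 14):
            d = np.linalg.norm(ca_of(fapc_model, res + 1) - ca_of(fapc_model, res))
            assert d == pytest.approx(3.8, abs=0.01)

    def test_rung_z_levels(self, fapc_model):
        for k, res in enumerate((1, 38, 75)):
            assert ca_of(fapc_model, res)[2] == pytest.approx(k * 4.75, abs=1e-9)

    def test_rung_to_rung_transform_is_identical_translation(self, fapc_model):
        shift_01 = np.array([ca_of(fapc_model, r + 37) - ca_of(fapc_model, r)
                             for r in range(1, 38)])
        shift_12 = np.array([ca_of(fapc_model, r + 74) - ca_of(fapc_model, r + 37)
                             for r in range(1, 38)])
        assert np.abs(shift_01 - shift_01[0]).max() < 1e-6
        assert np.abs(shift_12 - shift_01).max() < 1e-6

    def test_empty_rolemap_raises(self):
        rolemap = fc.RoleMap(sequence="", roles=[], rungs=[],
                             arrangement="two_sided", arc_length=5)
        with pytest.raises(BuildError):
            fc.build_solenoid(rolemap)

    def test_infeasible_arc_closure_raises(self):
        seg = make_segmentation(16)
        rolemap = fc.assign_roles(seg, "two_sided", arc_length=1)
        # one arc residue spans at most 2 x 3.8 A < 10 A sheet gap
        with pytest.raises(BuildError, match="arc"):
            fc.build_solenoid(rolemap)

    def test_three_sided_triangular_cross_section(self):
        seg = make_segmentation(37)
        rolemap = fc.assign_roles(seg, "three_sided", arc_length=4)
        model = fc.build_solenoid(rolemap)
        assert model.arrangement == "three_sided"
        assert fc.clash_check(model).count == 0


class TestStackMonomers:
    def test_single_copy_identity(self, fapc_model):
        assert fc.stack_monomers(fapc_model, 1) is fapc_model

    def test_trimer_rung_lattice(self, fapc_model, fapc_trimer):
        assert fapc_trimer.n_monomers == 3
        # equivalent residues across the monomer interface continue the lattice
        z0 = ca_of(fapc_trimer, 75, monomer=0)[2]
        z1 = ca_of(fapc_trimer, 1, monomer=1)[2]
        assert z1 - z0 == pytest.approx(4.75, abs=1e-9)

    def test_copies_are_pure_translations(self, fapc_model, fapc_trimer):
        a = fapc_trimer.coords[fapc_trimer.monomer == 0]
        b = fapc_trimer.coords[fapc_trimer.monomer == 1]
        diff = b - a
        assert np.abs(diff - diff[0]).max() < 1e-9  # rigid translation, RMSD 0


class TestCoreWidth:
    def test_fapc_width_matches_fiber_core(self, fapc_model):
        assert fc.measure_core_width(fapc_model) == pytest.approx(4.5, abs=0.5)

    def test_csga_width_narrower(self, csga_model):
        assert fc.measure_core_width(csga_model) == pytest.approx(3.0, abs=0.5)

    def test_single_residue_rung_zero_width(self):
        seq = "A" * 3
        rolemap = fc.RoleMap(sequence=seq, roles=["strand1", "arc", "arc"],
                             rungs=[[("strand1", 1, 1)]], arrangement="two_sided",
                             arc_length=0)
        # degenerate: a single-point rung has no extent
        model = fc.SolenoidModel(
            res_id=np.array([1]), atom_name=np.array(["CA"]),
            monomer=np.zeros(1, dtype=int), coords=np.zeros((1, 3)),
            rung_of={1: 0}, role_of={1: "strand1"}, arrangement="two_sided",
            n_monomers=1, params=fc.GeometryParams(), sequence=seq,
        )
        assert fc.measure_core_width(model) == 0.0

    def test_width_scales_linearly_with_strand_length(self):
        widths = []
        for n in range(5, 21):
            period = 2 * n + 4  # strands n + n, arcs 2 + 2
            seg = make_segmentation(period, n_repeats=2)
            rolemap = fc.assign_roles(seg, "two_sided", arc_length=2)
            widths.append(10 * fc.measure_core_width(fc.build_solenoid(rolemap)))
        increments = np.diff(widths)
        # each added residue widens the rung by ~ the axial projection; the
        # pleat alternates the arc chord with strand-length parity, so single
        # increments oscillate around 3.45 A while their mean converges to it
        assert np.all(increments > 0)
        assert np.all(np.abs(increments - 3.45) < 0.5)
        assert abs(increments.mean() - 3.45) < 0.05


class TestClashCheck:
    def test_default_builds_clash_free(self, fapc_model, csga_model, fapc_trimer):
        for model in (fapc_model, csga_model, fapc_trimer):
            assert fc.clash_check(model).count == 0

    def test_collapsed_sheet_separation_reports_clashes(self):
        seg = make_segmentation(37)
        rolemap = fc.assign_roles(seg, "two_sided", arc_length=5)
        params = fc.GeometryParams(sheet_separation=2.0)
        model = fc.build_solenoid(rolemap, params)
        report = fc.clash_check(model)
        assert report.count > 0
        roles = {fc_role for pair in report.pairs
                 for fc_role in (model.role_of[pair[0][0]], model.role_of[pair[1][0]])}
        assert roles & {"strand1", "strand2"}

    def test_empty_model_no_clashes(self):
        model = fc.SolenoidModel(
            res_id=np.array([], dtype=int), atom_name=np.array([]),
            monomer=np.array([], dtype=int), coords=np.zeros((0, 3)),
            rung_of={}, role_of={}, arrangement="two_sided", n_monomers=1,
            params=fc.GeometryParams(),
        )
        assert fc.clash_check(model).count == 0

    def test_sweep_repeat_lengths_clash_free(self):
        for period in range(15, 61, 5):
            for arrangement, arc in (("two_sided", 5), ("three_sided", 4)):
                n_sides = 2 if arrangement == "two_sided" else 3
                if period < n_sides * (1 + arc):
                    continue
                seg = make_segmentation(period, n_repeats=2)
                rolemap = fc.assign_roles(seg, arrangement, arc_length=arc)
                model = fc.build_solenoid(rolemap)
                assert fc.clash_check(model).count == 0, (period, arrangement)


class TestPdbIO:
    def test_rung_atom_records(self, fapc_model):
        buf = io.StringIO()
        fc.write_pdb(fapc_model, buf)
        atom_lines = [l for l in buf.getvalue().splitlines() if l.startswith("ATOM")]
        assert len(atom_lines) == 2 * 111
        assert all(l[21] == "A" for l in atom_lines)

    def test_trimer_chains(self, fapc_trimer):
        buf = io.StringIO()
        fc.write_pdb(fapc_trimer, buf)
        chains = {l[21] for l in buf.getvalue().splitlines() if l.startswith("ATOM")}
        assert chains == {"A", "B", "C"}

    def test_round_trip_coordinates(self, fapc_trimer):
        buf = io.StringIO()
        fc.write_pdb(fapc_trimer, buf)
        buf.seek(0)
        back = fc.read_pdb_model(buf)
        assert back.n_atoms == fapc_trimer.n_atoms
        # order-independent comparison: sort both by (chain, residue, atom)
        def key(m):
            return np.lexsort((m.atom_name, m.res_id, m.monomer))
        orig = fapc_trimer.coords[key(fapc_trimer)]
        rt = back.coords[key(back)]
        assert np.abs(orig - rt).max() <= 1e-3

    def test_fibril_axis_remark(self, fapc_model):
        buf = io.StringIO()
        fc.write_pdb(fapc_model, buf)
        assert "FIBRIL AXIS = +Z" in buf.getvalue()

    def test_empty_model_write_raises(self):
        model = fc.SolenoidModel(
            res_id=np.array([], dtype=int), atom_name=np.array([]),
            monomer=np.array([], dtype=int), coords=np.zeros((0, 3)),
            rung_of={}, role_of={}, arrangement="two_sided", n_monomers=1,
            params=fc.GeometryParams(),
        )
        with pytest.raises(ValueError):
            fc.write_pdb(model, io.StringIO())


class TestGeometryParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            fc.GeometryParams(ca_step=-1)
        with pytest.raises(ValueError):
            fc.GeometryParams(axial_projection=4.0)  # must be < ca_step

    def test_pleat_closes_ca_step(self):
        p = fc.GeometryParams()
        d = np.hypot(p.axial_projection, 2 * p.pleat_amplitude)
        assert d == pytest.approx(p.ca_step, abs=1e-12)
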