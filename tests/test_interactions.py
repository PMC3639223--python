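import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermotraj._elements import mass_of
from thermotraj.interactions import (
    PersistenceTable,
    average_hbond_count,
    detect_hbonds_frame,
    hbond_persistence,
    persistence_loss,
    persistent_count,
    salt_bridge_candidates,
    salt_bridge_persistence,
)
from thermotraj.io import AtomRecord, Structure, Topology, Trajectory, perceive_topology
from thermotraj.synthetic import generate_peptide, generate_trajectory

from .oracles import brute_force_hbonds, brute_force_salt_bridges


def _minimal_donor_acceptor(d_no, angle_deg):
    """Donor N at origin, H along +x; acceptor O at distance d_no rotated by
    angle_deg from the N->H direction (in the xy plane)."""
    ang = np.radians(angle_deg)
    atoms = [
        AtomRecord(1, "N", "N", "ALA", 1, "A", np.zeros(3), False, True),
        AtomRecord(2, "H", "H", "ALA", 1, "A", np.array([1.01, 0, 0]), True, True),
        AtomRecord(
            3, "O", "O", "ALA", 5, "A",
            d_no * np.array([np.cos(ang), np.sin(ang), 0.0]), False, True,
        ),
    ]
    structure = Structure(atoms=atoms)
    topo = Topology(donors=[(0, 1)], acceptors=[2], amide_hydrogens=[1])
    return structure, topo


class TestGeometricCriteria:
    @pytest.mark.parametrize(
        "d_no, angle, expected",
        [
            (2.9, 0.0, True),   # ideal linear bond
            (3.6, 0.0, False),  # distance cutoff
            (3.0, 35.0, False), # angle cutoff
            (3.49, 29.0, True), # just inside both
            (3.5, 0.0, False),  # tie at distance excluded (strict <)
            (3.0, 30.0, False), # tie at angle excluded (strict <)
        ],
    )
    def test_cutoff_semantics(self, d_no, angle, expected):
        structure, topo = _minimal_donor_acceptor(d_no, angle)
        events = detect_hbonds_frame(structure.positions, topo, structure)
        assert bool(events) is expected

    def test_within_residue_pair_excluded(self):
        structure, topo = _minimal_donor_acceptor(2.9, 0.0)
        atoms = list(structure.atoms)
        atoms[2] = AtomRecord(3, "O", "O", "ALA", 1, "A", atoms[2].position, False, True)
        same_res = Structure(atoms=atoms)
        assert detect_hbonds_frame(same_res.positions, topo, same_res) == []

    def test_matches_brute_force_on_random_frames(self, rng):
        peptide = generate_peptide(50, "helix")
        topo, peptide = perceive_topology(peptide)
        residue_of = [a.residue_number for a in peptide.atoms]
        base = peptide.positions
        for _ in range(100):
            frame = base + rng.normal(0, rng.uniform(0.05, 1.5), size=base.shape)
            got = {
                (e.donor_n, e.hydrogen, e.acceptor_o)
                for e in detect_hbonds_frame(frame, topo, peptide)
            }
            want = brute_force_hbonds(frame, topo.donors, topo.acceptors, residue_of)
            assert got == want

    def test_tightening_cutoffs_never_adds_bonds(self, rng):
        peptide = generate_peptide(30, "helix")
        topo, peptide = perceive_topology(peptide)
        frame = peptide.positions + rng.normal(0, 0.4, size=(peptide.n_atoms, 3))
        loose = len(detect_hbonds_frame(frame, topo, peptide, d_max=3.5, a_max=30))
        tight_d = len(detect_hbonds_frame(frame, topo, peptide, d_max=3.2, a_max=30))
        tight_a = len(detect_hbonds_frame(frame, topo, peptide, d_max=3.5, a_max=20))
        assert tight_d <= loose and tight_a <= loose


class TestCountsAndPersistence:
    def test_average_count_worked_example(self):
        # one pair present 51/100 frames, another 100/100 -> 1.51
        peptide = generate_peptide(12, "helix")
        schedule = {(5, 1): 0.51, (6, 2): 1.0}
        for i in range(7, 13):
            schedule[(i, i - 4)] = 0.0
        traj, _ = generate_trajectory(peptide, 100, schedule=schedule, seed=0)
        topo, peptide = perceive_topology(peptide)
        assert average_hbond_count(traj, topo, peptide) == pytest.approx(1.51, abs=1e-12)

    def test_static_frames_constant_count(self, helix12):
        peptide, topo = helix12
        traj = Trajectory(np.repeat(peptide.positions[None], 7, axis=0), 20.0)
        per_frame = [
            len(detect_hbonds_frame(traj.coords[f], topo, peptide)) for f in range(7)
        ]
        assert len(set(per_frame)) == 1
        assert average_hbond_count(traj, topo, peptide) == per_frame[0]

    def test_average_equals_fraction_sum_identity(self, rng):
        peptide = generate_peptide(25, "helix")
        topo, peptide = perceive_topology(peptide)
        coords = peptide.positions[None] + rng.normal(0, 0.6, size=(40, peptide.n_atoms, 3))
        traj = Trajectory(coords, 20.0)
        table = hbond_persistence(traj, topo, peptide)
        avg = average_hbond_count(traj, topo, peptide)
        assert avg == pytest.approx(table.total_fraction(), abs=1e-12)

    def test_planted_schedule_recovered_exactly(self):
        peptide = generate_peptide(15, "helix")
        schedule = {(5, 1): 0.73, (6, 2): 0.5, (7, 3): 0.0}
        traj, truth = generate_trajectory(peptide, 100, schedule=schedule, seed=4)
        topo, peptide = perceive_topology(peptide)
        table = hbond_persistence(traj, topo, peptide)
        measured = {}
        for (n_i, _, o_i), frac in table.fractions.items():
            pair = (peptide.atoms[n_i].residue_number, peptide.atoms[o_i].residue_number)
            measured[pair] = frac
        assert measured == truth.hbond_schedule
        assert measured[(5, 1)] == 0.73
        assert (7, 3) not in measured  # never-present pair omitted

    def test_window_larger_than_trajectory_rejected(self, helix12):
        peptide, topo = helix12
        traj = Trajectory(np.repeat(peptide.positions[None], 5, axis=0), 20.0)
        with pytest.raises(ValueError):
            average_hbond_count(traj, topo, peptide, window=6)


class TestPersistentCount:
    def test_strict_threshold_semantics(self):
        table = PersistenceTable(
            fractions={(0, 1, 2): 0.51, (3, 4, 5): 0.50, (6, 7, 8): 0.49},
            n_frames_analyzed=100,
        )
        assert persistent_count(table, 0.5) == 1

    def test_zero_threshold_counts_all_listed_pairs(self):
        table = PersistenceTable(
            fractions={(0, 1, 2): 0.01, (3, 4, 5): 1.0}, n_frames_analyzed=100
        )
        assert persistent_count(table, 0.0) == 2

    def test_invalid_threshold_rejected(self):
        table = PersistenceTable(fractions={}, n_frames_analyzed=1)
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                persistent_count(table, bad)

    @settings(deadline=None, max_examples=50)
    @given(
        fracs=st.lists(st.floats(min_value=0.001, max_value=1.0), min_size=1, max_size=30),
        t1=st.floats(min_value=0.0, max_value=0.99),
        t2=st.floats(min_value=0.0, max_value=0.99),
    )
    def test_monotone_in_threshold(self, fracs, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        table = PersistenceTable(
            fractions={(i, i, i): f for i, f in enumerate(fracs)},
            n_frames_analyzed=1000,
        )
        assert persistent_count(table, hi) <= persistent_count(table, lo)


class TestPersistenceLoss:
    def test_identical_tables_lose_nothing(self):
        t = PersistenceTable(fractions={(0, 1, 2): 0.8}, n_frames_analyzed=100)
        assert persistence_loss(t, t).empty

    def test_dropped_pair_listed_with_both_fractions(self):
        a = PersistenceTable(fractions={(0, 1, 2): 0.8}, n_frames_analyzed=100)
        b = PersistenceTable(fractions={(0, 1, 2): 0.3}, n_frames_analyzed=100)
        lost = persistence_loss(a, b)
        assert len(lost) == 1
        assert lost.iloc[0]["fraction_a"] == 0.8
        assert lost.iloc[0]["fraction_b"] == 0.3

    def test_planted_temperature_series_loss_recovered(self):
        # "cold" trajectory keeps 6 persistent pairs, "hot" drops 2 named ones
        peptide = generate_peptide(12, "helix")
        pairs = [(i, i - 4) for i in range(5, 13)]
        cold = {p: 0.9 if i < 6 else 0.0 for i, p in enumerate(pairs)}
        dropped = {pairs[4], pairs[5]}
        hot = {p: (0.2 if p in dropped else f) for p, f in cold.items()}
        traj_c, _ = generate_trajectory(peptide, 10, schedule=cold, seed=1)
        traj_h, _ = generate_trajectory(peptide, 10, schedule=hot, seed=2)
        topo, peptide = perceive_topology(peptide)
        table_c = hbond_persistence(traj_c, topo, peptide)
        table_h = hbond_persistence(traj_h, topo, peptide)
        lost = persistence_loss(table_c, table_h)
        lost_pairs = {
            (
                peptide.atoms[row.donor_n].residue_number,
                peptide.atoms[row.acceptor_o].residue_number,
            )
            for row in lost.itertuples()
        }
        assert lost_pairs == dropped


def _charged_pair_system(rng, n_frames=20, jitter=0.6):
    """An ASP carboxylate and a LYS ammonium nitrogen plus spectators."""
    def atom(serial, name, element, resname, resnum, pos):
        return AtomRecord(
            serial, name, element, resname, resnum, "A",
            np.asarray(pos, float), element == "H", False,
        )

    atoms = [
        atom(1, "OD1", "O", "ASP", 10, (0.0, 1.1, 0.0)),
        atom(2, "OD2", "O", "ASP", 10, (0.0, -1.1, 0.0)),
        atom(3, "NZ", "N", "LYS", 20, (2.8, 0.8, 0.0)),
        atom(4, "OE1", "O", "GLU", 30, (12.0, 1.1, 0.0)),
        atom(5, "OE2", "O", "GLU", 30, (12.0, -1.1, 0.0)),
        atom(6, "NE", "N", "ARG", 40, (20.0, 0.0, 0.0)),
        atom(7, "NH1", "N", "ARG", 40, (21.0, 1.0, 0.0)),
        atom(8, "NH2", "N", "ARG", 40, (21.0, -1.0, 0.0)),
    ]
    structure = Structure(atoms=atoms)
    topo, _ = perceive_topology(structure)
    base = structure.positions
    coords = base[None] + rng.normal(0, jitter, size=(n_frames, len(atoms), 3))
    return structure, topo, Trajectory(coords, 20.0)


class TestSaltBridges:
    def test_single_close_frame_makes_candidate(self, rng):
        structure, topo, traj = _charged_pair_system(rng, n_frames=5, jitter=0.0)
        cands = salt_bridge_candidates(traj, topo)
        assert (("A", 10, "ASP"), ("A", 20, "LYS")) in cands
        assert (("A", 30, "GLU"), ("A", 40, "ARG")) not in cands

    def test_never_close_is_not_candidate(self):
        rng = np.random.default_rng(0)
        structure, topo, traj = _charged_pair_system(rng, n_frames=5, jitter=0.0)
        # move the LYS N to 3.3 A from both oxygens' closest approach
        coords = traj.coords.copy()
        coords[:, 2, 0] = 4.6  # O..N distance becomes sqrt(4.6^2+1.1^2) > 3.3
        cands = salt_bridge_candidates(Trajectory(coords, 20.0), topo)
        assert not cands

    def test_com_marginal_geometry_retained(self):
        # both O-N atom distances ~3.3 A (outside 3.2 pre-screen on their own
        # frame), but COM(O1,O2)-N = 3.0 A: passes once pre-screened
        rng = np.random.default_rng(1)
        structure, topo, traj = _charged_pair_system(rng, n_frames=10, jitter=0.0)
        coords = traj.coords.copy()
        coords[:, 2, 0] = 3.0  # COM of oxygens is at origin; N at 3.0 A
        coords[0, 2, 0] = 3.1  # one frame close enough atomwise: sqrt(3.1^2+1.1^2)=3.29 < 3.2? no
        coords[0, 2, :] = (2.9, 0.5, 0.0)  # one genuinely close frame for the pre-screen
        traj2 = Trajectory(coords, 20.0)
        cands = salt_bridge_candidates(traj2, topo)
        assert (("A", 10, "ASP"), ("A", 20, "LYS")) in cands
        records = salt_bridge_persistence(traj2, topo, cands, structure)
        rec = next(r for r in records if r.acidic == ("A", 10, "ASP"))
        assert rec.retained
        assert rec.persistence_fraction == 1.0

    def test_exact_50_percent_rejected(self):
        rng = np.random.default_rng(2)
        structure, topo, traj = _charged_pair_system(rng, n_frames=10, jitter=0.0)
        coords = traj.coords.copy()
        coords[:5, 2, 0] = 3.0  # close half the frames
        coords[5:, 2, 0] = 6.0  # far the other half
        coords[0, 2, :] = (2.9, 0.5, 0.0)
        traj2 = Trajectory(coords, 20.0)
        cands = salt_bridge_candidates(traj2, topo)
        records = salt_bridge_persistence(traj2, topo, cands, structure)
        rec = next(r for r in records if r.acidic == ("A", 10, "ASP"))
        assert rec.persistence_fraction == 0.5
        assert not rec.retained

    def test_two_stage_filter_matches_brute_force(self, rng):
        structure, topo, traj = _charged_pair_system(rng, n_frames=30, jitter=0.8)
        masses = {i: mass_of(a.element) for i, a in enumerate(structure.atoms)}
        want_cands, want_retained = brute_force_salt_bridges(
            traj.coords, topo.carboxylate_groups, topo.basic_groups, masses
        )
        got_cands = salt_bridge_candidates(traj, topo)
        assert got_cands == want_cands
        records = salt_bridge_persistence(traj, topo, got_cands, structure)
        for rec in records:
            frac, retained = want_retained[(rec.acidic, rec.basic)]
            assert rec.persistence_fraction == pytest.approx(frac, abs=1e-12)
            assert rec.retained == retained
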