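"""Structure-to-CG mapping, native-contact detection, sequence-built DNA,
charge assignment, model topology generation and synthetic fixtures."""

import itertools

import numpy as np
import pytest

from rescg import builder
from rescg.dna_geometry import COMPLEMENT, compose_frames
from rescg.io.structure import AtomModel
from rescg.topology import Frame


# ---------------------------------------------------------------------------
# mapping count laws
# ---------------------------------------------------------------------------

def test_protein_mapping_one_bead_per_residue(helix_model, helix_cg):
    assert len(helix_cg) == 20
    assert all(n == "CA" for n in helix_cg.name)
    # bead sits on the Calpha atom
    ca = helix_model.positions[helix_model.name == "CA"]
    assert np.allclose(helix_cg.positions, ca)


def test_protein_mapping_skips_residues_without_ca(helix_model):
    drop = helix_model.name != "CA"
    keep = np.ones(len(helix_model), dtype=bool)
    # remove the CA of residue 5
    keep[(helix_model.resid == 5) & (helix_model.name == "CA")] = False
    model = AtomModel(*(np.asarray(getattr(helix_model, f))[keep]
                        for f in ("element", "name", "resname", "chain",
                                  "resid", "positions")))
    report = builder.MappingReport()
    cg = builder.map_protein(model, report)
    assert len(cg) == 19
    assert report.dropped == [("A", 5, "no CA atom")]


def test_nucleic_mapping_count_law(duplex):
    # 10-bp duplex: per strand 3n-1 = 29 -> 58 particles
    assert len(duplex.cgmap) == 58
    counts = {n: int(np.sum(duplex.cgmap.name == n))
              for n in ("DP", "DS", "DB")}
    assert counts == {"DP": 18, "DS": 20, "DB": 20}


def test_single_nucleotide_maps_to_two_beads():
    from rescg.dna_geometry import atoms_for, SITE_TEMPLATE
    rows = [(el, nm, "DA", "A", 1, pos)
            for nm, el, pos in atoms_for("A", 0)]
    model = AtomModel(
        element=np.array([r[0] for r in rows], dtype=object),
        name=np.array([r[1] for r in rows], dtype=object),
        resname=np.array([r[2] for r in rows], dtype=object),
        chain=np.array([r[3] for r in rows], dtype=object),
        resid=np.array([r[4] for r in rows], dtype=np.int64),
        positions=np.array([r[5] for r in rows]))
    cg = builder.map_nucleic(model, "dna")
    assert list(cg.name) == ["DS", "DB"]   # 5'-terminal phosphate dropped


def test_fifty_bp_duplex_counts():
    build = builder.build_dsdna_from_sequence("CG" * 25)
    assert len(build.cgmap) == 2 * (3 * 50 - 1) == 298
    n_nt = len(set(zip(build.cgmap.chain, build.cgmap.resid)))
    assert n_nt == 100


# ---------------------------------------------------------------------------
# native contacts
# ---------------------------------------------------------------------------

def brute_force_contacts(cgmap, cutoff, min_seq_sep=4):
    """Independent O(N^2) heavy-atom scan (the defining criterion)."""
    out = set()
    pos = cgmap.source.positions
    n = len(cgmap)
    for i in range(n):
        for j in range(i + 1, n):
            if (cgmap.chain[i] == cgmap.chain[j]
                    and abs(int(cgmap.resid[i]) - int(cgmap.resid[j]))
                    < min_seq_sep):
                continue
            di = pos[cgmap.groups[i]]
            dj = pos[cgmap.groups[j]]
            d2 = ((di[:, None, :] - dj[None, :, :]) ** 2).sum(-1)
            if d2.min() < cutoff ** 2:
                out.add((i, j))
    return out


def test_contacts_match_brute_force_scan(helix_cg):
    contacts = builder.detect_native_contacts(helix_cg, cutoff=6.5)
    got = {tuple(p) for p in contacts.idx}
    assert got == brute_force_contacts(helix_cg, 6.5)
    # sigma is the native site-site distance
    for (i, j), s in zip(contacts.idx, contacts.sigma):
        assert s == pytest.approx(np.linalg.norm(
            helix_cg.positions[i] - helix_cg.positions[j]))


def test_contact_cutoff_is_strict():
    def two_residue_model(gap):
        rows = []
        for r, x0 in ((1, 0.0), (6, gap)):
            rows += [("C", "CA", "ALA", "A", r, [x0, 0, 0]),
                     ("C", "CB", "ALA", "A", r, [x0, 1.5, 0])]
        return AtomModel(
            element=np.array([r[0] for r in rows], dtype=object),
            name=np.array([r[1] for r in rows], dtype=object),
            resname=np.array([r[2] for r in rows], dtype=object),
            chain=np.array([r[3] for r in rows], dtype=object),
            resid=np.array([r[4] for r in rows], dtype=np.int64),
            positions=np.array([r[5] for r in rows], dtype=float))

    near = builder.map_protein(two_residue_model(6.4))
    far = builder.map_protein(two_residue_model(6.6))
    assert len(builder.detect_native_contacts(near, 6.5).idx) == 1
    assert len(builder.detect_native_contacts(far, 6.5).idx) == 0


def test_contact_detection_order_independent(helix_model):
    # permute two copies of the helix presented in opposite chain order
    def shifted(model, chain, dz):
        return AtomModel(model.element.copy(), model.name.copy(),
                         model.resname.copy(),
                         np.array([chain] * len(model), dtype=object),
                         model.resid.copy(),
                         model.positions + np.array([0.0, 0.0, dz]))

    a, b = shifted(helix_model, "A", 0.0), shifted(helix_model, "B", 6.0)

    def catmodel(m1, m2):
        return AtomModel(*(np.concatenate([getattr(m1, f), getattr(m2, f)])
                           for f in ("element", "name", "resname", "chain",
                                     "resid", "positions")))

    cg_ab = builder.map_protein(catmodel(a, b))
    cg_ba = builder.map_protein(catmodel(b, a))
    set_ab = {(cg_ab.chain[i], int(cg_ab.resid[i]),
               cg_ab.chain[j], int(cg_ab.resid[j]))
              for i, j in builder.detect_native_contacts(cg_ab, 6.5).idx}
    set_ba = set()
    for i, j in builder.detect_native_contacts(cg_ba, 6.5).idx:
        key = (cg_ba.chain[i], int(cg_ba.resid[i]),
               cg_ba.chain[j], int(cg_ba.resid[j]))
        set_ba.add(tuple(sorted([key[:2], key[2:]]))[0] +
                   tuple(sorted([key[:2], key[2:]]))[1])
    set_ab = {tuple(sorted([k[:2], k[2:]]))[0]
              + tuple(sorted([k[:2], k[2:]]))[1] for k in set_ab}
    assert set_ab == set_ba


# ---------------------------------------------------------------------------
# sequence-to-structure DNA
# ---------------------------------------------------------------------------

def test_dsdna_complementary_strands(duplex):
    seq = duplex.sequence
    strand_b = [str(duplex.cgmap.residue[i])
                for i in duplex.base_cg_indices(1)]
    # strand II in its own 5'->3' order is the reverse complement
    assert "".join(strand_b) == "".join(COMPLEMENT[b] for b in seq[::-1])


def test_dsdna_rejects_bad_input():
    with pytest.raises(ValueError):
        builder.build_dsdna_from_sequence("CGXG")
    with pytest.raises(ValueError):
        builder.build_dsdna_from_sequence("A")


def test_consensus_insertion_reproduced():
    seq = "CG" * 21 + "TAAACAAT" + "CG" * 21   # TAAACAAT centered in poly-CG
    seq = seq[:50]
    assert len(seq) == 50
    build = builder.build_dsdna_from_sequence(seq)
    strand_a = "".join(str(build.cgmap.residue[i])
                       for i in build.base_cg_indices(0))
    assert "TAAACAAT" in strand_a
    assert len(build.cgmap) == 298


def test_uniform_step_table_composes_exact_helix():
    # all steps identical pure twist/rise -> closed-form helix
    twist, rise = 34.3, 3.32
    table = {a + b: (twist, 0.0, 0.0, 0.0, 0.0, rise)
             for a, b in itertools.product("ACGT", repeat=2)}
    build = builder.build_dsdna_from_sequence("ACGTACGTAC", step_table=table)
    o = build.frame_origins
    # rise: uniform spacing along a straight axis
    d = np.diff(o, axis=0)
    assert np.allclose(np.linalg.norm(d, axis=1), rise, atol=1e-6)
    axis = d / rise
    assert np.allclose(axis, axis[0], atol=1e-6)
    # twist: rotation angle between consecutive frames about the axis
    r = build.frame_rotations
    for k in range(len(o) - 1):
        rel = r[k].T @ r[k + 1]
        ang = np.degrees(np.arccos((np.trace(rel) - 1) / 2))
        assert ang == pytest.approx(twist, abs=1e-6)


# ---------------------------------------------------------------------------
# charges
# ---------------------------------------------------------------------------

def test_integer_charges_on_peptide():
    cg = builder.make_fixture("idp_chain", n=3, sequence="RGE", seed=0)
    top, _ = builder.generate_model_topology(cg, "hps")
    builder.assign_charges(top, "integer")
    assert list(top.particles.charge) == [1.0, 0.0, -1.0]


def test_duplex_phosphate_charges(dna_system):
    top, _, _ = dna_system
    charged = top.particles.charge != 0
    assert charged.sum() == 18                      # 3n-1 -> n-1 P per strand
    assert set(top.particles.name[charged]) == {"DP"}
    assert np.all(top.particles.charge[charged] == -1.0)


def test_fifty_bp_duplex_has_98_phosphates():
    build = builder.build_dsdna_from_sequence("CG" * 25)
    top, _ = builder.generate_model_topology(build.cgmap, "3spn2c")
    builder.assign_charges(top, "integer")
    assert int(np.sum(top.particles.charge == -1.0)) == 98


def test_file_charges_verbatim(helix_system, tmp_path):
    top, _, _ = helix_system
    lines = [f"{i + 1},{0.01 * (i - 10):.4f}" for i in range(20)]
    (tmp_path / "q.csv").write_text("\n".join(lines) + "\n")
    builder.assign_charges(top, "file", path=tmp_path / "q.csv")
    assert top.particles.charge[0] == pytest.approx(-0.10)
    assert top.particles.charge[19] == pytest.approx(0.09)
    (tmp_path / "bad.csv").write_text("999,1.0\n")
    with pytest.raises(ValueError, match="missing particle"):
        builder.assign_charges(top, "file", path=tmp_path / "bad.csv")


# ---------------------------------------------------------------------------
# model topologies
# ---------------------------------------------------------------------------

def test_hps_topology_term_list():
    cg = builder.make_fixture("idp_chain", n=100, seed=4)
    top, _ = builder.generate_model_topology(cg, "hps")
    assert len(top.bonds.idx) == 99
    assert len(top.angles.idx) == 0
    assert len(top.dihedrals.idx) == 0
    assert len(top.contacts.idx) == 0
    assert np.all(top.particles.eps > 0)


def test_aicg2p_flexible_tails_get_local_terms_only(helix_cg):
    flexible = {"A": set(range(1, 4)) | set(range(17, 21))}
    top, _ = builder.generate_model_topology(helix_cg, "aicg2+",
                                             flexible=flexible)
    flex_idx = {i for i in range(20)
                if int(helix_cg.resid[i]) in flexible["A"]}
    for i, j in top.contacts.idx:
        assert not ({int(i), int(j)} & flex_idx)
    for i, k in top.gauss13.idx:
        assert not ({int(i), int(k)} & flex_idx)
    # gaussian dihedrals avoid flexible residues; tabulated ones cover all
    gaussian = top.dihedrals.idx[top.dihedrals.func == 21]
    for quad in gaussian:
        assert not (set(int(x) for x in quad) & flex_idx)
    tabulated = top.dihedrals.idx[top.dihedrals.func == 22]
    assert len(tabulated) == 17


def test_3spn2c_record_counts_for_2bp():
    build = builder.build_dsdna_from_sequence("AT")
    top, _ = builder.generate_model_topology(build.cgmap, "3spn2c")
    # one stack record per intra-strand step
    assert len(top.stacks.idx) == 2
    bp = top.basepairs
    assert len(bp.base_idx) == 4
    # native WC partner exclusions: one per base pairing
    assert len(top.extra_exclusions) == 2


def test_model_molecule_class_mismatch(helix_cg, duplex):
    with pytest.raises(ValueError):
        builder.generate_model_topology(helix_cg, "3spn2c")
    with pytest.raises(ValueError):
        builder.generate_model_topology(duplex.cgmap, "aicg2+")


def test_builder_output_passes_validation(helix_system, dna_system):
    for top in (helix_system[0], dna_system[0]):
        top.validate()   # raises on any inconsistency


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def test_helix_fixture_geometry():
    model = builder.make_fixture("helix_ca", n=20)
    cg = builder.map_protein(model)
    d = np.linalg.norm(np.diff(cg.positions, axis=0), axis=1)
    assert np.allclose(d, 3.8, atol=0.1)


def test_idp_chain_deterministic():
    a = builder.make_fixture("idp_chain", n=30, seed=9)
    b = builder.make_fixture("idp_chain", n=30, seed=9)
    assert np.array_equal(a.positions, b.positions)
    d = np.linalg.norm(np.diff(a.positions, axis=0), axis=1)
    assert np.allclose(d, 3.8, atol=1e-9)


def test_slab_fixture_box_and_overlap():
    chain = builder.make_fixture("idp_chain", n=20, seed=2)
    box = np.array([180.0, 180.0, 2000.0])   # 18 x 18 x 200 nm
    placed, out_box = builder.make_fixture(
        "multi_chain_slab", chain_positions=chain.positions, box=box,
        n_chains=40, seed=3, min_dist=4.0)
    assert np.array_equal(out_box, box)
    assert placed.shape == (40, 20, 3)
    from scipy.spatial import cKDTree
    pts = placed.reshape(-1, 3) % box
    tree = cKDTree(pts, boxsize=box)
    for a, b in tree.query_pairs(4.0):
        assert a // 20 == b // 20    # only intra-chain pairs that close


def test_slab_impossible_packing_raises():
    chain = builder.make_fixture("idp_chain", n=50, seed=2)
    with pytest.raises(RuntimeError, match="packing"):
        builder.make_fixture("multi_chain_slab",
                             chain_positions=chain.positions,
                             box=np.array([40.0, 40.0, 40.0]),
                             n_chains=200, seed=1, min_dist=6.0,
                             max_tries=50)


def test_mapping_report_totals(helix_model):
    report = builder.MappingReport()
    builder.map_protein(helix_model, report)
    assert report.total == 20
    assert report.per_chain == {"A": {"protein": 20}}
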