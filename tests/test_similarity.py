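"""Similarity metrics: Kabsch, Qw, Q_template, GDT-TS, contact maps.

Oracles: hand-enumerated pair sums for the Q metrics on collinear toys,
a numerical rotation-search oracle for Kabsch, direct counting for GDT-TS
and brute-force pair enumeration for contact maps.
"""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from mrprep import (
    AlignmentMap,
    ConsistencyError,
    ContactMap,
    PreconditionError,
    contact_map,
    contact_overlap,
    gdt_ts,
    kabsch_superpose,
    make_ideal_helix,
    q_template,
    qw,
)

from conftest import collinear_chain, model_from_ca

# frozen hand evaluations (explicit arithmetic over the qualifying pairs,
# computed independently of the implementation)
QW_TOY_5RES = 0.8178492326457135
QT_TOY_6RES = 0.8000612599983602


def _rigid(model, rng, scale=10.0):
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.normal(scale=scale, size=3)
    return model.with_coords(ca=model.ca @ rot.T + trans)


# ---------------------------------------------------------------------------
# Kabsch


def test_kabsch_identity():
    xyz = make_ideal_helix(10).ca
    rot, trans, rmsd = kabsch_superpose(xyz, xyz)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(trans, 0.0, atol=1e-10)
    assert rmsd == pytest.approx(0.0, abs=1e-12)


def test_kabsch_recovers_rigid_motion():
    xyz = make_ideal_helix(10).ca
    r90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    target = xyz @ r90.T + [5.0, 0.0, 0.0]
    _, _, rmsd = kabsch_superpose(xyz, target)
    assert rmsd == pytest.approx(0.0, abs=1e-9)


def test_kabsch_rotation_is_proper(rng):
    """Reflections are never returned, even for near-planar point sets."""
    mobile = rng.normal(size=(4, 3))
    mobile[:, 2] *= 0.01
    target = rng.normal(size=(4, 3))
    rot, _, _ = kabsch_superpose(mobile, target)
    assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_matches_rotation_search_oracle(rng):
    """Independent oracle: numerical minimisation over rotation vectors."""
    mobile = np.array(
        [[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [5.0, 3.0, 0.5], [2.0, 4.0, 3.0]]
    )
    target = mobile + rng.normal(scale=0.4, size=mobile.shape)
    _, _, rmsd = kabsch_superpose(mobile, target)

    pc = mobile - mobile.mean(axis=0)
    qc = target - target.mean(axis=0)

    def cost(rotvec):
        moved = pc @ Rotation.from_rotvec(rotvec).as_matrix().T
        return np.sqrt(np.mean(np.sum((moved - qc) ** 2, axis=1)))

    best = min(
        minimize(cost, x0=rng.normal(scale=2.0, size=3), method="Nelder-Mead",
                 options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000}).fun
        for _ in range(8)
    )
    assert rmsd == pytest.approx(best, abs=1e-4)
    assert rmsd <= best + 1e-9  # Kabsch is the optimum


def test_kabsch_never_worse_than_raw_rmsd(rng):
    for _ in range(10):
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        _, _, rmsd = kabsch_superpose(a, b)
        assert rmsd <= raw + 1e-12


def test_kabsch_preconditions():
    with pytest.raises(ConsistencyError):
        kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
    with pytest.raises(PreconditionError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# Qw


def test_qw_self_is_one(helix20):
    assert qw(helix20, helix20) == pytest.approx(1.0, abs=1e-12)


def test_qw_is_symmetric(rng):
    a = model_from_ca(rng.normal(scale=5.0, size=(12, 3)))
    b = model_from_ca(rng.normal(scale=5.0, size=(12, 3)))
    assert qw(a, b) == pytest.approx(qw(b, a), abs=1e-12)


def test_qw_hand_enumerated_toy():
    """5 collinear residues, residue 5 pushed 1 Å: 3 qualifying pairs."""
    a = collinear_chain(5)
    ca = a.ca.copy()
    ca[4, 2] += 1.0
    b = a.with_coords(ca=ca)
    assert qw(a, b) == pytest.approx(QW_TOY_5RES, abs=1e-6)


def test_qw_rigid_motion_invariance(helix20, rng):
    moved = _rigid(helix20, rng)
    noisy = helix20.with_coords(ca=helix20.ca + rng.normal(scale=0.5, size=(20, 3)))
    assert qw(helix20, moved) == pytest.approx(1.0, abs=1e-9)
    assert qw(moved, noisy) == pytest.approx(qw(helix20, noisy), abs=1e-9)


def test_qw_decreases_with_noise_amplitude(helix20):
    """Monotone in expectation: average over 20 seeds per amplitude."""
    amplitudes = [0.2, 0.6, 1.2, 2.5]
    means = []
    for amp in amplitudes:
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            noisy = helix20.with_coords(
                ca=helix20.ca + rng.normal(scale=amp, size=(20, 3))
            )
            vals.append(qw(helix20, noisy))
        means.append(np.mean(vals))
    assert all(x > y for x, y in zip(means, means[1:]))


def test_qw_needs_four_residues():
    tiny = collinear_chain(3)
    with pytest.raises(PreconditionError):
        qw(tiny, tiny)


# ---------------------------------------------------------------------------
# Q_template


def test_q_template_self_is_one(helix20):
    assert q_template(helix20, helix20, AlignmentMap.identity(helix20)) == (
        pytest.approx(1.0, abs=1e-12)
    )


def test_q_template_hand_enumerated_partial_alignment():
    """6 collinear residues, residues 1-4 and 6 aligned, residue 6 pushed 1 Å."""
    template = collinear_chain(6)
    ca = template.ca.copy()
    ca[5, 2] += 1.0
    model = template.with_coords(ca=ca)
    alignment = AlignmentMap(((1, 1), (2, 2), (3, 3), (4, 4), (6, 6)))
    assert q_template(model, template, alignment) == pytest.approx(
        QT_TOY_6RES, abs=1e-6
    )


def test_q_template_theta_excludes_short_template_distances():
    """A template pair below 2 Å drops out of sum and normalisation alike."""
    # residues 1..5 at 3.8 Å spacing, but template residue 5 folded back to
    # sit 1.9 Å from residue 1 (off-axis) → pair (1,5) excluded, (2,5) kept
    tca = np.zeros((5, 3))
    tca[:, 2] = [0.0, 3.8, 7.6, 11.4, 0.0]
    tca[4, 0] = 1.9
    template = model_from_ca(tca)
    model = collinear_chain(5)
    full = AlignmentMap.identity(model)
    value = q_template(model, template, full)

    # independent enumeration with explicit arithmetic
    mca = model.ca
    total, n = 0.0, 0
    for i in range(5):
        for j in range(i + 1, 5):
            if j - i < 3:
                continue
            r_n = float(np.linalg.norm(tca[j] - tca[i]))
            if r_n < 2.0:
                continue
            r = np.linalg.norm(mca[j] - mca[i])
            sigma = (1 + (j - i)) ** 0.15
            total += math.exp(-((r - r_n) ** 2) / (2 * sigma**2))
            n += 1
    assert n == 2  # (1,4) and (2,5); (1,5) was Θ-excluded
    assert value == pytest.approx(total / n, abs=1e-12)


def test_q_template_agrees_with_qw_on_clean_full_alignment(rng):
    """With a full alignment and no Θ-excluded pairs both metrics share the
    same pair set, so they must agree."""
    a = make_ideal_helix(15)
    b = a.with_coords(ca=a.ca + rng.normal(scale=0.5, size=(15, 3)))
    # helix template distances at sep ≥ 3 all exceed 2 Å
    value_qt = q_template(b, a, AlignmentMap.identity(a))
    value_qw = qw(b, a)
    assert value_qt == pytest.approx(value_qw, abs=1e-12)


def test_q_template_no_qualifying_pairs():
    model = collinear_chain(4)
    with pytest.raises(PreconditionError):
        q_template(model, model, AlignmentMap(((1, 1), (2, 2))))


def test_alignment_map_rejects_duplicates():
    with pytest.raises(ConsistencyError):
        AlignmentMap(((1, 1), (1, 2)))


# ---------------------------------------------------------------------------
# GDT-TS


def test_gdt_identical_is_one(helix20):
    assert gdt_ts(helix20, helix20) == pytest.approx(1.0)


def test_gdt_counting_oracle():
    """Deviations [0.5, 1.5, 3, 9] → (1/4 + 2/4 + 3/4 + 3/4)/4 = 0.5625."""
    ref = collinear_chain(4)
    ca = ref.ca.copy()
    for i, d in enumerate([0.5, 1.5, 3.0, 9.0]):
        ca[i, 0] += d
    model = ref.with_coords(ca=ca)
    assert gdt_ts(model, ref, presuperpose=False) == pytest.approx(0.5625)


def test_gdt_all_beyond_eight_is_zero():
    ref = collinear_chain(5)
    model = ref.with_coords(ca=ref.ca + [20.0, 0.0, 0.0])
    assert gdt_ts(model, ref, presuperpose=False) == 0.0


def test_gdt_presuperposition_removes_rigid_offset(rng):
    ref = make_ideal_helix(15)
    moved = _rigid(ref, rng)
    assert gdt_ts(moved, ref, presuperpose=True) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# contact maps


@pytest.mark.parametrize("dist, present", [(9.4, True), (9.5, True), (9.6, False)])
def test_contact_boundary_at_cutoff(dist, present):
    ca = np.zeros((4, 3))
    ca[:, 2] = [0.0, 3.0, 6.0, 0.0]
    ca[3] = [dist, 0.0, 6.0]  # residue 4 at `dist` from residue 1? no — from 3
    ca[3] = ca[0] + [dist, 0.0, 0.0]
    model = model_from_ca(ca)
    cm = contact_map(model)
    assert ((1, 4) in cm.contacts) is present


def test_contact_min_seq_sep_excludes_near_pairs():
    model = collinear_chain(5, spacing=1.0)  # every pair within 9.5 Å
    cm = contact_map(model, min_seq_sep=3)
    assert all(j - i >= 3 for i, j in cm.contacts)
    assert (1, 3) not in cm.contacts  # (i, i+2) excluded regardless of distance


def test_helix_contact_count_matches_enumeration(helix20):
    cm = contact_map(helix20)
    expected = set()
    ca = helix20.ca
    for i in range(20):
        for j in range(i + 1, 20):
            if j - i >= 3 and np.linalg.norm(ca[j] - ca[i]) <= 9.5:
                expected.add((i + 1, j + 1))
    assert cm.contacts == frozenset(expected)
    assert expected  # helices have (i, i+3) and (i, i+4) contacts
    assert (1, 5) in cm.contacts  # Cα(i)–Cα(i+4) < 9.5 Å in a helix


def test_contact_map_rigid_invariance(helix20, rng):
    moved = _rigid(helix20, rng)
    assert contact_map(moved).contacts == contact_map(helix20).contacts


def test_contact_overlap_set_arithmetic():
    a = {(1, 4), (2, 6)}
    b = {(2, 6), (3, 7)}
    pa = ContactMap(10, frozenset(a), 9.5, 3)
    pb = ContactMap(10, frozenset(b), 9.5, 3)
    assert contact_overlap(pa, pa) == (1.0, 1.0, 1.0)
    precision, recall, jaccard = contact_overlap(pa, pb)
    assert (precision, recall) == (0.5, 0.5)
    assert jaccard == pytest.approx(1 / 3)
    pc = ContactMap(10, frozenset({(5, 9)}), 9.5, 3)
    assert contact_overlap(pa, pc) == (0.0, 0.0, 0.0)


def test_contact_overlap_parameter_mismatch():
    pa = ContactMap(10, frozenset(), 9.5, 3)
    pb = ContactMap(10, frozenset(), 8.0, 3)
    with pytest.raises(ConsistencyError):
        contact_overlap(pa, pb)


def test_contact_overlap_empty_prediction_flagged_nan():
    empty = ContactMap(10, frozenset(), 9.5, 3)
    full = ContactMap(10, frozenset({(1, 5)}), 9.5, 3)
    precision, recall, _ = contact_overlap(empty, full)
    assert math.isnan(precision) and recall == 0.0
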