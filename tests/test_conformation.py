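"""Ramachandran classification, strand detection, propensity tables."""

import collections

import numpy as np
import pytest

from alphasheet.conformation import (
    PropensityTable,
    RamachandranRegion as R,
    StrandSegment,
    carbonyl_alignment,
    classify_chain,
    classify_region,
    detect_alpha_strands,
    mirror_propensities,
    mirror_region,
    propensity_from_samples,
)
from alphasheet.geometry import ConformationalEnsemble, measure_dihedrals


@pytest.mark.parametrize(
    "phi,psi,expected",
    [
        (-60.0, -45.0, R.ALPHA_R),
        (60.0, 45.0, R.ALPHA_L),
        (-120.0, 130.0, R.BETA),
        (120.0, -130.0, R.MIRROR_BETA),
        # half-open boundary convention: 0 counts as nonnegative
        (0.0, 0.0, R.ALPHA_L),
        (-1e-9, 0.0, R.BETA),
        (None, 30.0, R.UNDEFINED),
        (float("nan"), 30.0, R.UNDEFINED),
    ],
)
def test_classify_region(phi, psi, expected):
    assert classify_region(phi, psi) is expected


def test_classification_mirror_symmetry_on_grid():
    """classify(−φ,−ψ) == mirror(classify(φ,ψ)) over a 1° grid.

    The grid sits at half-degree offsets: the quadrant boundaries themselves
    are half-open (assigned to the nonnegative side) and are the only points
    where exact inversion symmetry is deliberately given up.
    """
    grid = np.arange(-179.5, 180.0, 1.0)
    for phi in grid:
        for psi in grid[::4]:
            assert classify_region(-phi, -psi) is mirror_region(classify_region(phi, psi))


def test_polygonal_regions_supported():
    core_alpha_r = [(-160.0, -120.0), (-20.0, -120.0), (-20.0, 30.0), (-160.0, 30.0)]
    regions = [(R.ALPHA_R, core_alpha_r)]
    assert classify_region(-60.0, -45.0, regions=regions) is R.ALPHA_R
    assert classify_region(60.0, 45.0, regions=regions) is R.UNDEFINED


def test_single_frame_occupancy_is_unit(alpha_template):
    for c in classify_chain(alpha_template):
        assert sum(c.occupancy.values()) == pytest.approx(1.0)
        assert c.occupancy[c.modal] == pytest.approx(1.0)


def test_two_frame_split_occupancy():
    """A residue αR in one frame and αL in the other gets 0.5/0.5 occupancy."""
    from alphasheet.geometry import DihedralTriple, build_backbone

    def four_mer(mid):
        dih = [DihedralTriple(None, 130.0, 180.0),
               DihedralTriple(*mid, 180.0),
               DihedralTriple(-120.0, 130.0, 180.0),
               DihedralTriple(-120.0, None, None)]
        return build_backbone("AAAA", dih)

    ens = ConformationalEnsemble(frames=[four_mer((-60.0, -45.0)), four_mer((60.0, 45.0))])
    occ = classify_chain(ens)[1].occupancy
    assert occ[R.ALPHA_R] == pytest.approx(0.5)
    assert occ[R.ALPHA_L] == pytest.approx(0.5)
    for c in classify_chain(ens):
        assert sum(c.occupancy.values()) == pytest.approx(1.0)


def test_ensemble_occupancy_equals_counting_oracle(alpha_ensemble_small):
    """Occupancies equal brute-force per-frame label counting exactly."""
    result = classify_chain(alpha_ensemble_small)
    n_frames = len(alpha_ensemble_small.frames)
    counts = [collections.Counter() for _ in result]
    for frame in alpha_ensemble_small.frames:
        for i, d in enumerate(measure_dihedrals(frame)):
            counts[i][classify_region(d.phi, d.psi)] += 1
    for c, cnt in zip(result, counts):
        for region in R:
            assert c.occupancy[region] == pytest.approx(cnt[region] / n_frames, abs=1e-12)
        assert c.modal is max(
            list(R), key=lambda r: (cnt[r] / n_frames, -list(R).index(r))
        )


# ---------------------------------------------------------------------------
# strand detection


def brute_force_strands(labels, min_len):
    """Exhaustive substring scan: every maximal alternating αL/αR run."""
    found = []
    n = len(labels)
    alpha = {R.ALPHA_R, R.ALPHA_L}
    for i in range(n):
        for j in range(i, n):
            seg = labels[i : j + 1]
            ok = all(s in alpha for s in seg) and all(
                seg[k] != seg[k + 1] for k in range(len(seg) - 1)
            )
            if not ok:
                continue
            left_ext = i > 0 and labels[i - 1] in alpha and labels[i - 1] != seg[0]
            right_ext = j < n - 1 and labels[j + 1] in alpha and labels[j + 1] != seg[-1]
            if not left_ext and not right_ext and len(seg) >= min_len:
                found.append((i + 1, j + 1))
    return sorted(set(found))


def test_alpha_template_has_two_strands(alpha_template):
    segs = detect_alpha_strands(classify_chain(alpha_template))
    assert len(segs) == 2
    # strands cover the classifiable strand residues (terminal residues have
    # undefined φ or ψ and cannot be labeled)
    assert (segs[0].start, segs[0].end) == (2, 6)
    assert (segs[1].start, segs[1].end) == (9, 13)


def test_beta_template_has_no_alpha_strands(beta_template):
    assert detect_alpha_strands(classify_chain(beta_template)) == []


def test_embedded_run_matches_scan_oracle():
    labels = [R.BETA, R.ALPHA_R, R.ALPHA_L, R.ALPHA_R, R.ALPHA_L, R.ALPHA_R,
              R.BETA, R.ALPHA_L, R.ALPHA_L]
    segs = detect_alpha_strands(labels, min_len=4)
    assert [(s.start, s.end) for s in segs] == [(2, 6)] == brute_force_strands(labels, 4)


def test_random_label_strings_match_scan_oracle():
    rng = np.random.default_rng(51)
    pool = list(R)
    for _ in range(50):
        labels = [pool[k] for k in rng.integers(0, len(pool), size=30)]
        segs = detect_alpha_strands(labels, min_len=4)
        assert [(s.start, s.end) for s in segs] == brute_force_strands(labels, 4)
        # maximality / disjointness
        for a, b in zip(segs, segs[1:]):
            assert a.end < b.start


# ---------------------------------------------------------------------------
# carbonyl / amide alignment


def test_alignment_extremes(alpha_template):
    seg = StrandSegment(2, 5, R.ALPHA_R)
    uniform = alpha_template.copy()
    v = np.array([0.0, 0.0, 1.231])
    for res in uniform.residues:
        res.atoms["O"] = res.atoms["C"] + v
    assert carbonyl_alignment(uniform, seg).carbonyl_order == pytest.approx(1.0)
    for k, res in enumerate(uniform.residues):
        res.atoms["O"] = res.atoms["C"] + (v if k % 2 == 0 else -v)
    assert carbonyl_alignment(uniform, seg).carbonyl_order == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        carbonyl_alignment(uniform, StrandSegment(3, 3, R.ALPHA_R))


def test_alpha_strand_more_aligned_than_beta(alpha_template, beta_template):
    seg = StrandSegment(2, 6, R.ALPHA_R)
    a = carbonyl_alignment(alpha_template, seg)
    b = carbonyl_alignment(beta_template, seg)
    assert a.carbonyl_order > b.carbonyl_order
    assert a.amide_order > b.amide_order


# ---------------------------------------------------------------------------
# propensities


def test_propensity_concentrated_sample():
    table = propensity_from_samples({("A", "L"): [(-60.0, -45.0)] * 10})
    assert table.probability("A", "L", R.ALPHA_R) == 1.0
    assert table.modal_region("A", "L") is R.ALPHA_R
    assert table.counts[("A", "L")] == 10


def test_propensity_matches_counting_oracle():
    rng = np.random.default_rng(61)
    pts = [(float(p), float(s)) for p, s in rng.uniform(-180.0, 180.0, size=(500, 2))]
    table = propensity_from_samples({("V", "L"): pts})
    counts = collections.Counter(classify_region(p, s) for p, s in pts)
    for region in R:
        assert table.probability("V", "L", region) == pytest.approx(
            counts[region] / len(pts), abs=1e-12
        )


def test_l_alanine_alpha_r_dominant_mirrors_to_alpha_l():
    """An αR-dominant L entry gives an αL-dominant D entry with the same mass."""
    rng = np.random.default_rng(71)
    pts = [(-60.0 + float(rng.normal(0, 15)), -45.0 + float(rng.normal(0, 15)))
           for _ in range(200)]
    table = propensity_from_samples({("A", "L"): pts})
    assert table.modal_region("A", "L") is R.ALPHA_R
    d_table = mirror_propensities(table)
    assert d_table.modal_region("A", "D") is R.ALPHA_L
    assert d_table.probability("A", "D", R.ALPHA_L) == table.probability("A", "L", R.ALPHA_R)


def test_mirror_is_involution_and_preserves_mass():
    rng = np.random.default_rng(81)
    samples = {
        (code, "L"): [(float(p), float(s)) for p, s in rng.uniform(-180, 180, (50, 2))]
        for code in "AVK"
    }
    samples[("G", None)] = [(float(p), float(s)) for p, s in rng.uniform(-180, 180, (50, 2))]
    table = propensity_from_samples(samples)
    twice = mirror_propensities(mirror_propensities(table))
    assert twice.entries == table.entries
    for row in mirror_propensities(table).entries.values():
        assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)
    # Gly passes through unchanged
    assert mirror_propensities(table).entries[("G", None)] == table.entries[("G", None)]


def test_symmetric_table_is_fixed_point():
    table = PropensityTable(
        entries={("A", "L"): {R.ALPHA_R: 0.3, R.ALPHA_L: 0.3, R.BETA: 0.2,
                              R.MIRROR_BETA: 0.2, R.UNDEFINED: 0.0}},
        counts={("A", "L"): 4},
    )
    mirrored = mirror_propensities(table)
    assert mirrored.entries[("A", "D")] == table.entries[("A", "L")]


def test_propensity_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(91)
    samples = {("A", "L"): [(float(p), float(s)) for p, s in rng.uniform(-180, 180, (64, 2))],
               ("G", None): [(-80.0, 90.0)] * 3}
    table = propensity_from_samples(samples)
    path = tmp_path / "prop.tsv"
    table.to_tsv(path)
    back = PropensityTable.from_tsv(path)
    assert back.counts == table.counts
    for key, row in table.entries.items():
        for region in R:
            assert back.entries[key][region] == pytest.approx(row[region], abs=1e-12)
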