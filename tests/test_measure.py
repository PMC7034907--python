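"""Inclusion segmentation, statistics and ground-truth recovery."""

from collections import deque
from itertools import product

import numpy as np
import pytest

from natronid.attenuation import linear_attenuation
from natronid.measure import recovery_report, segment_inclusions
from natronid.phantom import (
    Ellipsoid,
    PhantomSpec,
    degrade,
    generate_phantom,
    mummy_preset,
    realize,
)

NEIGHBOURS26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def flood_fill_components(mask):
    """Brute-force 26-connected labelling (independent oracle)."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    sizes = []
    current = 0
    for idx in zip(*np.nonzero(mask)):
        if labels[idx]:
            continue
        current += 1
        size = 0
        queue = deque([idx])
        labels[idx] = current
        while queue:
            z, y, x = queue.popleft()
            size += 1
            for dz, dy, dx in NEIGHBOURS26:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= c < s for c, s in zip(n, mask.shape)) and mask[n] and not labels[n]:
                    labels[n] = current
                    queue.append(n)
        sizes.append(size)
    return current, sorted(sizes)


def _spheres_spec(centers, radius=5.0, shape=(40, 40, 40)):
    prims = [Ellipsoid(c, (radius,) * 3, "halite") for c in centers]
    return PhantomSpec(shape=shape, voxel_size_um=10.0, background="balm",
                       primitives=prims)


def test_single_sphere_exact_mean(registry, table):
    vol = generate_phantom(_spheres_spec([(20.0, 20.0, 20.0)], radius=6.0),
                           146.1, table, registry)
    seg = segment_inclusions(vol, threshold=0.25)
    expected = linear_attenuation(registry.get("halite"), 146.1, table)
    assert len(seg) == 1
    assert seg.inclusions[0].mean_mu == pytest.approx(expected, abs=1e-6)
    assert seg.inclusions[0].max_mu == pytest.approx(expected, abs=1e-6)
    assert seg.inclusions[0].centroid == pytest.approx((20.0, 20.0, 20.0), abs=0.1)


def test_threshold_above_maximum_gives_empty_result():
    vol = generate_phantom(_spheres_spec([(20.0, 20.0, 20.0)]), 146.1)
    seg = segment_inclusions(vol, threshold=float(vol.mu.max()) + 1.0)
    assert len(seg) == 0
    assert seg.mean_of_means is None


def test_component_count_against_flood_fill_oracle():
    """Disjoint spheres stay separate, overlapping ones merge — and the label
    counts/sizes agree with an independent BFS flood fill on a 40³ grid."""
    disjoint = generate_phantom(_spheres_spec([(12, 12, 12), (28, 28, 28)]), 146.1)
    merged = generate_phantom(_spheres_spec([(18, 20, 20), (24, 20, 20)]), 146.1)
    for vol, expected_n in [(disjoint, 2), (merged, 1)]:
        seg = segment_inclusions(vol, threshold=0.25, min_size=1)
        n_oracle, sizes_oracle = flood_fill_components(vol.mu > 0.25)
        assert len(seg) == expected_n == n_oracle
        assert sorted(s.voxel_count for s in seg.inclusions) == sizes_oracle


def test_segmentation_monotone_in_threshold():
    vol = realize(mummy_preset(seed=9, shape=(48, 64, 64), n_inclusions=6), 146.1)
    sizes_total = []
    for thr in (0.22, 0.25, 0.28, 0.31):
        seg = segment_inclusions(vol, threshold=thr, min_size=1)
        sizes_total.append(sum(s.voxel_count for s in seg.inclusions))
    assert sizes_total == sorted(sizes_total, reverse=True)


def test_min_size_discards_small_components(registry, table):
    vol = generate_phantom(_spheres_spec([(20, 20, 20)], radius=1.4), 146.1,
                           table, registry)
    n_above = int((vol.mu > 0.25).sum())
    assert 0 < n_above < 27
    assert len(segment_inclusions(vol, threshold=0.25, min_size=27)) == 0
    assert len(segment_inclusions(vol, threshold=0.25, min_size=1)) == 1


def test_exclude_mask_removes_region():
    vol = generate_phantom(_spheres_spec([(12, 12, 12), (28, 28, 28)]), 146.1)
    exclude = np.zeros(vol.mu.shape, dtype=bool)
    exclude[:20] = True
    seg = segment_inclusions(vol, threshold=0.25, exclude_mask=exclude)
    assert len(seg) == 1


def test_perfect_recovery_on_clean_phantom():
    spec = mummy_preset(seed=4, psf_sigma=0.0, noise_sigma=0.0)
    vol = generate_phantom(spec, 146.1)
    bone = vol.labels == 1
    seg = segment_inclusions(vol, threshold=0.25, exclude_mask=bone)
    rep = recovery_report(seg, vol, exclude_labels=(0, 1))
    assert rep.precision == 1.0 and rep.recall == 1.0
    assert all(abs(b) < 1e-6 for b in rep.bias.values())
    assert all(r < 1e-6 for r in rep.rmse.values())


def test_recall_on_default_degraded_preset():
    from scipy.ndimage import binary_dilation

    vol = realize(mummy_preset(seed=42), 146.1)
    exclude = binary_dilation(vol.labels == 1, iterations=3)
    seg = segment_inclusions(vol, threshold=0.25, exclude_mask=exclude)
    rep = recovery_report(seg, vol, exclude_labels=(0, 1))
    assert rep.recall >= 0.9
    assert rep.precision >= 0.9


def test_shuffled_truth_labels_keep_geometric_matching():
    """Matching is geometric: permuting ground-truth label ids changes nothing."""
    vol = realize(mummy_preset(seed=8, shape=(48, 64, 64), n_inclusions=6), 146.1)
    seg = segment_inclusions(vol, threshold=0.25)
    base = recovery_report(seg, vol, exclude_labels=(0, 1))
    # permute inclusion label ids consistently in labels and ground_truth
    perm = {0: 0, 1: 1}
    incl = [k for k in vol.ground_truth if k not in (0, 1)]
    for old, new in zip(incl, reversed(incl)):
        perm[old] = new
    shuffled_labels = np.vectorize(perm.get)(vol.labels).astype(np.uint16)
    shuffled_truth = {perm[k]: v for k, v in vol.ground_truth.items()}
    from dataclasses import replace

    shuffled = replace(vol, labels=shuffled_labels, ground_truth=shuffled_truth)
    other = recovery_report(seg, shuffled, exclude_labels=(0, 1))
    assert other.precision == base.precision
    assert other.recall == base.recall


def test_noise_limited_recovery_on_noise_only_degradation():
    """Without blur the error of each recovered mean is pure noise averaging:
    standardised by noise_sigma/√(interior count) the RMS error stays ~1."""
    sigma = 0.01
    spec = mummy_preset(seed=21, psf_sigma=0.0, noise_sigma=sigma)
    vol = generate_phantom(spec, 146.1)
    noisy = degrade(vol, 0.0, sigma, seed=21)
    seg = segment_inclusions(noisy, threshold=0.25, exclude_mask=noisy.labels == 1)
    rep = recovery_report(seg, noisy, exclude_labels=(0, 1))
    assert rep.recall == 1.0
    assert all(abs(b) < sigma for b in rep.bias.values())
    standardised = []
    for s in seg.inclusions:
        lab = int(vol.labels[tuple(int(round(c)) for c in s.centroid)])
        true_mu = vol.ground_truth[lab]["mu"]
        z = (s.mean_mu - true_mu) * np.sqrt(s.interior_voxel_count) / sigma
        standardised.append(z)
    assert np.sqrt(np.mean(np.square(standardised))) < 2.0
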