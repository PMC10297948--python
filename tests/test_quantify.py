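"""Cell detection, counting, double-positive matching, image cytometry."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from foltme import quantify, slidesim, stains
from foltme.compartments import compartment_masks

DETECT_KW = dict(min_scale=2.0, max_scale=7.0, threshold=0.08)


def _gaussian_blob(shape, center, sigma=2.0, amp=1.0):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    return amp * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                        / (2 * sigma**2))


def _match_to_truth(det, truth_centers, radius):
    """Greedy one-to-one matching of detections to true centers."""
    if det.empty or len(truth_centers) == 0:
        return 0
    tree = cKDTree(truth_centers)
    used = set()
    hits = 0
    d, idx = tree.query(det[["row", "col"]].to_numpy())
    for dist, j in sorted(zip(d, idx)):
        if dist <= radius and j not in used:
            used.add(j)
            hits += 1
    return hits


@pytest.fixture(scope="module")
def detections(slide_truth, unmixed_rounds):
    masks = compartment_masks(slide_truth.follicle_mask)
    out = {}
    for marker, (rnd, _) in slide_truth.panel.items():
        if marker == "CD21":
            continue
        det = quantify.detect_cells(unmixed_rounds[rnd]["chromogen"],
                                    marker, **DETECT_KW)
        out[marker] = quantify.assign_compartment(det, masks)
    return out


class TestDetectCells:
    def test_blank_channel_no_detections(self):
        det = quantify.detect_cells(np.zeros((64, 64)), "CD68", **DETECT_KW)
        assert len(det) == 0

    def test_invalid_scale_order_rejected(self):
        with pytest.raises(ValueError):
            quantify.detect_cells(np.zeros((8, 8)), min_scale=5, max_scale=5)

    def test_two_separated_blobs_found_at_centers(self):
        ch = (_gaussian_blob((80, 80), (20, 20))
              + _gaussian_blob((80, 80), (60, 55)))
        det = quantify.detect_cells(ch, "X", **DETECT_KW)
        assert len(det) == 2
        found = sorted(map(tuple, det[["row", "col"]].to_numpy()))
        for got, want in zip(found, [(20, 20), (60, 55)]):
            assert np.hypot(got[0] - want[0], got[1] - want[1]) < 2.0

    def test_recall_and_precision_on_synthetic_slide(self, slide_truth,
                                                     detections):
        truth_centers = np.array([c.center
                                  for c in slide_truth.cells_of("CD68")])
        det = detections["CD68"]
        radius = slide_truth.cells_of("CD68")[0].radius
        hits = _match_to_truth(det, truth_centers, radius)
        recall = hits / len(truth_centers)
        precision = hits / len(det)
        assert recall >= 0.95
        assert precision >= 0.90


class TestAssignCompartment:
    def test_detection_inside_follicle_is_if(self, slide_truth):
        mask = compartment_masks(slide_truth.follicle_mask)
        rr, cc = np.nonzero(slide_truth.follicle_mask)
        det = pd.DataFrame([{"marker": "X", "row": float(rr[0]),
                             "col": float(cc[0]), "scale": 3.0,
                             "peak_concentration": 1.0, "compartment": "",
                             "roi_id": "r"}])
        out = quantify.assign_compartment(det, mask)
        assert out["compartment"].iloc[0] == "IF"

    def test_empty_if_mask_makes_all_ef(self, rng):
        mask = compartment_masks(np.zeros((50, 50), bool))
        det = pd.DataFrame({"marker": "X", "row": rng.uniform(0, 49, 10),
                            "col": rng.uniform(0, 49, 10), "scale": 3.0,
                            "peak_concentration": 1.0, "compartment": "",
                            "roi_id": "r"})
        out = quantify.assign_compartment(det, mask)
        assert (out["compartment"] == "EF").all()

    def test_agreement_with_ground_truth_labels(self, slide_truth,
                                                detections):
        det = detections["CD68"]
        truth_cells = slide_truth.cells_of("CD68")
        centers = np.array([c.center for c in truth_cells])
        labels = np.array([c.compartment for c in truth_cells])
        tree = cKDTree(centers)
        d, idx = tree.query(det[["row", "col"]].to_numpy())
        matched = d <= truth_cells[0].radius
        agree = (det["compartment"].to_numpy()[matched]
                 == labels[idx[matched]]).mean()
        assert agree >= 0.98


class TestCounts:
    def test_zero_detections_zero_count(self):
        det = pd.DataFrame(columns=quantify.DETECTION_COLUMNS)
        out = quantify.counts_per_hpf(det, "P1", "CD68", "IF",
                                      roi_ids=["r0"])
        assert out["count"].tolist() == [0]

    def test_counts_equal_bruteforce_filter(self, detections):
        det = pd.concat([d.assign(roi_id="roi0")
                         for d in detections.values()], ignore_index=True)
        for marker in ("CD68", "CD163"):
            for comp in ("IF", "EF"):
                out = quantify.counts_per_hpf(det, "P1", marker, comp,
                                              roi_ids=["roi0"])
                brute = len([1 for _, r in det.iterrows()
                             if r["marker"] == marker
                             and r["compartment"] == comp])
                assert out["count"].iloc[0] == brute

    def test_compartment_counts_are_exhaustive_and_disjoint(self,
                                                            detections):
        det = detections["CD68"].assign(roi_id="roi0")
        n_if = quantify.counts_per_hpf(det, "P", "CD68", "IF",
                                       roi_ids=["roi0"])["count"].iloc[0]
        n_ef = quantify.counts_per_hpf(det, "P", "CD68", "EF",
                                       roi_ids=["roi0"])["count"].iloc[0]
        assert n_if + n_ef == len(det)

    def test_unexpected_roi_count_flagged(self, detections):
        det = detections["CD68"].assign(roi_id="roi0")
        out = quantify.counts_per_hpf(det, "P", "CD68", "IF",
                                      roi_ids=["roi0"], expected_rois=10)
        assert out["flagged"].all()


class TestDoublePositive:
    def test_close_pair_matched(self):
        a = pd.DataFrame({"row": [10.0], "col": [10.0]})
        b = pd.DataFrame({"row": [10.5], "col": [10.8]})
        pairs = quantify.match_double_positive(a, b, radius=5)
        assert len(pairs) == 1

    def test_disjoint_clouds_no_pairs(self, rng):
        a = pd.DataFrame({"row": rng.uniform(0, 10, 20),
                          "col": rng.uniform(0, 10, 20)})
        b = pd.DataFrame({"row": rng.uniform(50, 60, 20),
                          "col": rng.uniform(50, 60, 20)})
        assert len(quantify.match_double_positive(a, b, radius=5)) == 0

    def test_invalid_radius_rejected(self):
        a = pd.DataFrame({"row": [0.0], "col": [0.0]})
        with pytest.raises(ValueError):
            quantify.match_double_positive(a, a, radius=0)

    def test_matches_bruteforce_mutual_nn(self, rng):
        a = pd.DataFrame({"row": rng.uniform(0, 50, 40),
                          "col": rng.uniform(0, 50, 40)})
        b = pd.DataFrame({"row": rng.uniform(0, 50, 35),
                          "col": rng.uniform(0, 50, 35)})
        radius = 4.0
        pa = a.to_numpy(); pb = b.to_numpy()
        d = np.linalg.norm(pa[:, None] - pb[None, :], axis=2)
        brute = set()
        for i in range(len(pa)):
            j = int(np.argmin(d[i]))
            if d[i, j] <= radius and int(np.argmin(d[:, j])) == i:
                brute.add((i, j))
        pairs = quantify.match_double_positive(a, b, radius)
        got = set(zip(pairs["index_a"], pairs["index_b"]))
        assert got == brute

    def test_coexpression_fraction_recovered(self, unmixed_rounds,
                                             slide_truth):
        # doubled-up slide with configured 40% CD163-on-CD68 co-expression
        cfg = slidesim.SlideConfig(
            roi_size=300, pixel_size_um=1.0,
            densities={"CD68": {"IF": 0, "EF": 70.0},
                       "CD163": {"IF": 0, "EF": 50.0}},
            coexpression={("CD68", "CD163"): 0.4})
        truth = slidesim.generate_slide(cfg, seed=21)
        M = stains.StainMatrix.hax()
        dets = {}
        for marker, rnd in (("CD68", 1), ("CD163", 2)):
            img = slidesim.render_round(truth, rnd)
            ch = stains.deconvolve(stains.rgb_to_od(img), M).channel("AEC")
            dets[marker] = quantify.detect_cells(ch, marker, **DETECT_KW)
        pairs = quantify.match_double_positive(dets["CD68"], dets["CD163"],
                                               radius=3.0)
        frac = len(pairs) / len(dets["CD163"])
        assert abs(frac - 0.4) <= 0.05


class TestCytometry:
    def test_all_cells_above_threshold_gate_100(self):
        table = pd.DataFrame({"CD8": [0.5, 0.9, 0.7]})
        assert quantify.gate_percent(table, "CD8", 0.1) == 100.0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="no cells"):
            quantify.gate_percent(pd.DataFrame({"CD8": []}), "CD8", 0.5)
        with pytest.raises(ValueError, match="no cells"):
            quantify.cytometry_table({"CD8": pd.DataFrame(
                columns=quantify.DETECTION_COLUMNS)}, {}, 5.0)

    def test_gate_equals_bruteforce_count(self, rng):
        table = pd.DataFrame({"CD163": rng.uniform(0, 1, 200)})
        thr = 0.35
        brute = 100.0 * sum(1 for v in table["CD163"] if v > thr) / 200
        assert quantify.gate_percent(table, "CD163", thr) == brute

    def test_table_merges_double_positives(self):
        # two markers, one shared cell: 3 detections -> 2 objects
        ch_a = _gaussian_blob((60, 60), (20, 20))
        ch_b = (_gaussian_blob((60, 60), (20.6, 20.4))
                + _gaussian_blob((60, 60), (45, 45)))
        det_a = quantify.detect_cells(ch_a, "A", **DETECT_KW)
        det_b = quantify.detect_cells(ch_b, "B", **DETECT_KW)
        table = quantify.cytometry_table({"A": det_a, "B": det_b},
                                         {"A": ch_a, "B": ch_b},
                                         match_radius=4.0)
        assert len(table) == 2
        shared = table.loc[table["A"] > 0.5]
        assert len(shared) == 1
        assert shared["B"].iloc[0] > 0.5
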