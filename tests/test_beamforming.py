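"""Beamforming tests: CSD estimation, DICS localization, voxel
clustering/ROI construction, LCMV virtual sensors."""
import numpy as np
import pytest

from thetaflow import beamforming as bf
from thetaflow import synthio
from thetaflow.exceptions import (
    ConfigurationError,
    IncompleteROIError,
    NumericalError,
    ResolutionError,
)
from thetaflow.preprocess import EpochedEEG

FS = 256.0


def make_epochs(data):
    n_t = data.shape[2]
    return EpochedEEG(data, FS, (0.0, n_t / FS * 1000.0), "cue",
                      [f"c{i}" for i in range(data.shape[1])])


class TestCSD:
    def test_identical_sinusoids_fully_coherent(self):
        t = np.arange(512) / FS
        sig = np.sin(2 * np.pi * 4.5 * t)
        data = np.tile(sig, (20, 2, 1))
        csd = bf.compute_csd(make_epochs(data), 4.5)
        m = csd.matrix
        coh = np.abs(m[0, 1]) ** 2 / (m[0, 0].real * m[1, 1].real)
        assert coh == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_low_coherence(self):
        cohs = []
        for seed in range(10):
            g = np.random.default_rng(seed)
            data = g.normal(size=(500, 2, 256))
            m = bf.compute_csd(make_epochs(data), 4.5).matrix
            cohs.append(np.abs(m[0, 1]) ** 2
                        / (m[0, 0].real * m[1, 1].real))
        assert np.mean(cohs) < 0.05

    def test_diagonal_matches_welch_band_power(self):
        """A unit sinusoid's CSD diagonal equals the Welch amplitude
        estimate at the same frequency within 5%."""
        from scipy.signal import welch

        t = np.arange(1024) / FS
        amp = 3.0
        sig = amp * np.sin(2 * np.pi * 8.0 * t)
        data = np.tile(sig, (5, 1, 1))
        csd = bf.compute_csd(make_epochs(data), 8.0)
        f, p = welch(sig, fs=FS, nperseg=1024)
        # density -> amplitude^2: 2 * integral over the spectral peak
        # (the Hann window spreads the line over a few bins)
        peak = np.argmin(np.abs(f - 8.0))
        amp2 = 2 * p[peak - 3:peak + 4].sum() * (f[1] - f[0])
        assert csd.matrix[0, 0].real == pytest.approx(amp2, rel=0.05)
        assert csd.matrix[0, 0].real == pytest.approx(amp ** 2, rel=0.05)

    def test_window_too_short_rejected(self):
        data = np.zeros((3, 2, 64))
        with pytest.raises(ResolutionError):
            bf.compute_csd(make_epochs(data), 4.5)

    def test_hermitian_psd_enforced(self):
        with pytest.raises(NumericalError):
            bf.CSD(np.array([[1.0, 2.0], [0.5, 1.0]]), 4.5, (0, 1000), 1)


def project_source(head, voxel, src, noise_sd, rng):
    """trials x sensors x time data for one point source."""
    data = head.leadfield[:, voxel][None, :, None] * src[:, None, :]
    return data + rng.normal(0, noise_sd, data.shape)


class TestDICS:
    def test_point_source_recovery(self, head16):
        rng = np.random.default_rng(0)
        vstar = 77
        t = np.arange(512) / FS
        src = np.stack([np.sin(2 * np.pi * 4.5 * t + rng.uniform(0, 7))
                        for _ in range(30)])
        data = project_source(head16, vstar, src, 1e-6, rng)
        csd = bf.compute_csd(make_epochs(data), 4.5)
        pmap = bf.dics_power(csd, head16, 1e-6)
        assert int(np.argmax(pmap.power)) == vstar

    def test_two_sources_both_local_maxima(self, head16):
        rng = np.random.default_rng(1)
        va, vb = 40, 180
        t = np.arange(512) / FS
        n_tr = 40
        data = np.zeros((n_tr, head16.n_sensors, len(t)))
        for v in (va, vb):
            src = np.stack([np.sin(2 * np.pi * 4.5 * t
                                   + rng.uniform(0, 2 * np.pi))
                            for _ in range(n_tr)])
            data += head16.leadfield[:, v][None, :, None] * src[:, None, :]
        data += rng.normal(0, 0.01, data.shape)
        pmap = bf.dics_power(bf.compute_csd(make_epochs(data), 4.5),
                             head16, 0.01)

        def is_local_max(v):
            d = np.linalg.norm(head16.voxel_coords
                               - head16.voxel_coords[v], axis=1)
            neigh = np.flatnonzero((d > 0)
                                   & (d <= head16.grid_spacing * 1.01))
            return np.all(pmap.power[v] >= pmap.power[neigh])

        assert is_local_max(va) and is_local_max(vb)

    def test_noise_only_map_is_flat(self, head16):
        ratios = []
        for seed in range(10):
            g = np.random.default_rng(seed)
            data = g.normal(size=(50, head16.n_sensors, 256))
            pmap = bf.dics_power(bf.compute_csd(make_epochs(data), 4.5),
                                 head16, 0.05)
            ratios.append(pmap.power.max() / np.median(pmap.power))
        assert max(ratios) < 5.0

    def test_unit_gain_constraint(self, head16, rng):
        data = rng.normal(size=(20, head16.n_sensors, 256))
        csd = bf.compute_csd(make_epochs(data), 4.5)
        c = np.real(csd.matrix).copy()
        c[np.diag_indices_from(c)] += 0.05 * np.mean(np.diag(c))
        w = bf._unit_gain_filters(csd.matrix, head16.leadfield, 0.05)
        gains = np.einsum("cv,cv->v", w, head16.leadfield)
        assert np.abs(gains - 1.0).max() < 1e-8

    def test_singular_covariance_advises_lambda(self, head16):
        data = np.zeros((2, head16.n_sensors, 256))
        data[:, 0, :] = 1.0  # rank-1
        ep = make_epochs(data)
        with pytest.raises(NumericalError, match="lambda"):
            bf.dics_power(bf.compute_csd(ep, 4.5), head16, 0.0)


class TestThreshold:
    def test_exact_count_without_ties(self):
        mask = bf.threshold_top_percent(np.arange(100.0), 3)
        assert mask.sum() == 3
        assert mask[97:].all()

    def test_all_equal_all_selected(self):
        mask = bf.threshold_top_percent(np.ones(50), 3)
        assert mask.all()

    def test_ceil_rule(self):
        mask = bf.threshold_top_percent(np.arange(1.0, 201.0), 3)
        assert mask.sum() == 6            # ceil(0.03 * 200)
        assert np.flatnonzero(mask).min() == 194

    def test_invalid_pct(self):
        with pytest.raises(ConfigurationError):
            bf.threshold_top_percent(np.arange(10.0), 0)


def naive_dbscan(coords, eps, min_samples):
    """Textbook DBSCAN, written independently as an oracle."""
    n = len(coords)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = [len(nb) >= min_samples for nb in neighbors]
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for q in neighbors[j]:
                if labels[q] == -1:
                    labels[q] = cid
                    stack.append(q)
        cid += 1
    return labels


def same_partition(a, b):
    """Cluster labelings equal up to renaming (noise fixed at -1)."""
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


class TestClustering:
    def test_two_separated_groups(self, rng):
        g1 = rng.normal(0, 1, (10, 3))
        g2 = rng.normal(0, 1, (10, 3)) + 100.0
        labels = bf.cluster_voxels(np.vstack([g1, g2]), eps=5.0,
                                   min_samples=3)
        assert set(labels) == {0, 1}

    def test_isolated_voxel_is_noise(self):
        coords = np.vstack([np.zeros((5, 3)) + np.arange(5)[:, None] * 0.1,
                            [[50.0, 50.0, 50.0]]])
        labels = bf.cluster_voxels(coords, eps=1.0, min_samples=3)
        assert labels[-1] == -1

    def test_matches_naive_dbscan_on_marginal_ring(self, rng):
        """Ring of points at spacing ~eps, where chaining decisions are
        delicate: sklearn output must match the textbook algorithm."""
        for seed in range(10):
            g = np.random.default_rng(seed)
            ang = np.sort(g.uniform(0, 2 * np.pi, 30))
            ring = np.stack([10 * np.cos(ang), 10 * np.sin(ang),
                             np.zeros(30)], axis=1)
            extra = g.normal(0, 8, (15, 3))
            coords = np.vstack([ring, extra])
            eps = 2.2
            ours = bf.cluster_voxels(coords, eps=eps, min_samples=3)
            oracle = naive_dbscan(coords, eps, 3)
            assert same_partition(ours, oracle)


class TestROIs:
    def test_pure_clusters_map_to_their_labels(self, head16):
        atl = head16.region_voxels("ATL")[:5]
        ifc = head16.region_voxels("IFC")[:5]
        idx = np.concatenate([atl, ifc])
        clusters = np.array([0] * 5 + [1] * 5)
        rois = bf.rois_from_clusters(clusters, idx, head16,
                                     roi_names=("ATL", "IFC"))
        assert set(rois.names) == {"ATL", "IFC"}
        assert np.array_equal(rois.rois["ATL"], np.sort(atl))

    def test_majority_vote(self, head16):
        ic = head16.region_voxels("IC")[:6]
        other = head16.region_voxels("OTHER")[:4]
        idx = np.concatenate([ic, other])
        rois = bf.rois_from_clusters(np.zeros(10, int), idx, head16,
                                     roi_names=("IC",))
        assert set(rois.names) == {"IC"}

    def test_tie_breaks_lexicographically(self, head16):
        atl = head16.region_voxels("ATL")[:3]
        ic = head16.region_voxels("IC")[:3]
        idx = np.concatenate([atl, ic])
        rois = bf.rois_from_clusters(np.zeros(6, int), idx, head16,
                                     roi_names=("ATL",),
                                     exclude_labels=())
        # 50/50 ATL vs IC: "ATL" < "IC" lexicographically
        assert rois.provenance[0]["majority_label"] == "ATL"
        assert len(rois.rois["ATL"]) == 6  # the whole cluster follows

    def test_subcortical_voxels_dropped(self, head16):
        sub = head16.region_voxels("SUBCORTICAL")
        atl = head16.region_voxels("ATL")[:4]
        idx = np.concatenate([atl, sub])
        clusters = np.zeros(len(idx), int)
        rois = bf.rois_from_clusters(clusters, idx, head16,
                                     roi_names=("ATL",))
        assert not set(sub) & set(rois.rois["ATL"])

    def test_missing_roi_raises_naming_it(self, head16):
        atl = head16.region_voxels("ATL")[:4]
        with pytest.raises(IncompleteROIError, match="IFC"):
            bf.rois_from_clusters(np.zeros(4, int), atl, head16,
                                  roi_names=("ATL", "IFC"))

    def test_noise_voxels_excluded(self, head16):
        atl = head16.region_voxels("ATL")[:6]
        clusters = np.array([0, 0, 0, -1, -1, 0])
        rois = bf.rois_from_clusters(clusters, atl, head16,
                                     roi_names=("ATL",))
        assert len(rois.rois["ATL"]) == 4


class TestLCMV:
    def test_noiseless_source_reconstructed(self, head16, rng):
        atl = head16.region_voxels("ATL")
        vstar = int(atl[0])
        src = rng.standard_normal((10, 512))
        data = project_source(head16, vstar, src, 1e-9, rng)
        vs = bf.lcmv_virtual_sensors(make_epochs(data), head16,
                                     bf.ROISet({"ATL": atl}), 1e-8)
        r = np.corrcoef(vs.data[:, 0, :].ravel(), src.ravel())[0, 1]
        assert abs(r) > 0.99

    def test_source_outside_rois_leaks_little(self, rng):
        # full 60-channel montage: leakage suppression needs the spatial
        # resolution the real recording setup provides
        head = synthio.make_toy_leadfield(60, (6, 6, 6), seed=0)
        other = head.region_voxels("OTHER")
        far = int(other[np.argmax(np.linalg.norm(
            head.voxel_coords[other] - head.voxel_coords[
                head.region_voxels("ATL")].mean(axis=0), axis=1))])
        src = rng.standard_normal((20, 512))
        data = project_source(head, far, src, 0.01, rng)
        vs = bf.lcmv_virtual_sensors(
            make_epochs(data), head,
            bf.ROISet({"ATL": head.region_voxels("ATL")}), 0.05)
        r = np.corrcoef(vs.data[:, 0, :].ravel(), src.ravel())[0, 1]
        assert abs(r) < 0.3

    def test_two_rois_driven_independently_separate(self, head16):
        rs = []
        for seed in range(10):
            g = np.random.default_rng(seed)
            atl = head16.region_voxels("ATL")
            ifc = head16.region_voxels("IFC")
            va = int(atl[len(atl) // 2])
            vb = int(ifc[len(ifc) // 2])
            sa = g.standard_normal((15, 512))
            sb = g.standard_normal((15, 512))
            noise_sd = np.abs(head16.leadfield[:, [va, vb]]).mean() / 10
            data = (head16.leadfield[:, va][None, :, None] * sa[:, None, :]
                    + head16.leadfield[:, vb][None, :, None] * sb[:, None, :]
                    + g.normal(0, noise_sd,
                               (15, head16.n_sensors, 512)))
            vs = bf.lcmv_virtual_sensors(
                make_epochs(data), head16,
                bf.ROISet({"ATL": atl, "IFC": ifc}), 0.05)
            rs.append(abs(np.corrcoef(vs.data[:, 0, :].ravel(),
                                      vs.data[:, 1, :].ravel())[0, 1]))
        assert np.mean(rs) < 0.2

    def test_roi_set_determinism(self, head16, rng):
        data = rng.normal(size=(10, head16.n_sensors, 512))
        ep = make_epochs(data)
        pmaps = []
        for _ in range(2):
            csd = bf.compute_csd(ep, 4.5)
            pmap = bf.dics_power(csd, head16, 0.05)
            mask = bf.threshold_top_percent(pmap, 10)
            idx = np.flatnonzero(mask)
            labels = bf.cluster_voxels(head16.voxel_coords[idx],
                                       eps=1.5 * head16.grid_spacing)
            pmaps.append((idx, labels))
        assert np.array_equal(pmaps[0][0], pmaps[1][0])
        assert np.array_equal(pmaps[0][1], pmaps[1][1])


class TestROIThetaPower:
    def test_constant_sinusoid_power_flat_across_phases(self):
        t = np.arange(1024) / FS
        sig = np.sin(2 * np.pi * 4.5 * t)
        vs = bf.VirtualSensorSeries(np.tile(sig, (4, 1, 1)), FS, ["ATL"])
        p_all = bf.roi_theta_power(vs)
        vs_first = bf.VirtualSensorSeries(
            np.tile(sig[:512], (4, 1, 1)), FS, ["ATL"])
        p_first = bf.roi_theta_power(vs_first)
        assert p_all[0] == pytest.approx(p_first[0], rel=0.02)

    def test_amplitude_doubling_quadruples_power(self):
        t = np.arange(1024) / FS
        sig = np.sin(2 * np.pi * 4.5 * t)
        p1 = bf.roi_theta_power(bf.VirtualSensorSeries(
            np.tile(sig, (2, 1, 1)), FS, ["x"]))
        p2 = bf.roi_theta_power(bf.VirtualSensorSeries(
            np.tile(2 * sig, (2, 1, 1)), FS, ["x"]))
        assert p2[0] == pytest.approx(4 * p1[0], rel=1e-6)

    def test_mixed_signal_matches_fourier_band_oracle(self):
        t = np.arange(2048) / FS
        sig = (1.5 * np.sin(2 * np.pi * 4.5 * t)
               + 0.8 * np.sin(2 * np.pi * 11.0 * t))
        p = bf.roi_theta_power(bf.VirtualSensorSeries(
            np.tile(sig, (1, 1, 1)), FS, ["x"]))
        spec = np.fft.rfft(sig)
        freqs = np.fft.rfftfreq(len(sig), 1 / FS)
        amp = 2 * np.abs(spec[np.argmin(np.abs(freqs - 4.5))]) / len(sig)
        assert p[0] == pytest.approx(amp ** 2, rel=0.05)
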