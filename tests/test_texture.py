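"""Texture inventory: histogram, GLCM, GRLM, DWT features vs independent oracles."""

import math

import numpy as np
import pytest

from texomri.phantom import make_fixture
from texomri.preprocessing import NormalizationParams, QuantizedROI
from texomri.texture import (
    DWTConfig,
    GLCM_FEATURE_NAMES,
    GLCMConfig,
    GRLMConfig,
    dwt_features,
    extract_all,
    extract_features,
    feature_names,
    glcm,
    glcm_features,
    grlm_features,
    histogram_features,
)


def _roi(grid, mask=None, n_levels=None):
    grid = np.asarray(grid, dtype=np.int32)
    if mask is None:
        mask = np.ones(grid.shape, bool)
    if n_levels is None:
        n_levels = int(grid.max()) + 1
    return QuantizedROI(
        grid=grid,
        mask=np.asarray(mask, bool),
        n_levels=n_levels,
        params=NormalizationParams(mu=float(grid.mean()), sigma=float(grid.std())),
    )


# --------------------------------------------------------------------------
# brute-force oracle: dense pair loop + plain-formula statistics


def glcm_oracle(grid, mask, offset, n_levels, symmetric=True):
    rows, cols = grid.shape
    dr, dc = offset
    P = np.zeros((n_levels, n_levels))
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                P[grid[r, c], grid[r2, c2]] += 1
                if symmetric:
                    P[grid[r2, c2], grid[r, c]] += 1
    total = P.sum()
    return P / total if total else P


def glcm_stats_oracle(P):
    L = P.shape[0]
    i, j = np.mgrid[0:L, 0:L]
    px, py = P.sum(axis=1), P.sum(axis=0)
    mu_x, mu_y = (i * P).sum(), (j * P).sum()
    sd_x = math.sqrt((((i - mu_x) ** 2) * P).sum())
    sd_y = math.sqrt((((j - mu_y) ** 2) * P).sum())
    p_sum = np.zeros(2 * L - 1)
    p_diff = np.zeros(L)
    for a in range(L):
        for b in range(L):
            p_sum[a + b] += P[a, b]
            p_diff[abs(a - b)] += P[a, b]

    def ent(v):
        v = v[v > 0]
        return float(-(v * np.log(v)).sum())

    sa = (np.arange(2 * L - 1) * p_sum).sum()
    mu_d = (np.arange(L) * p_diff).sum()
    hx, hy, hxy = ent(px), ent(py), ent(P.ravel())
    pipj = np.outer(px, py)
    ok = (P > 0) & (pipj > 0)
    hxy1 = float(-(P[ok] * np.log(pipj[ok])).sum())
    return {
        "ACOR": float((i * j * P).sum()),
        "CON": float((((i - j) ** 2) * P).sum()),
        "COR": 0.0 if sd_x == 0 or sd_y == 0 else float(
            ((i * j * P).sum() - mu_x * mu_y) / (sd_x * sd_y)
        ),
        "CP": float((((i + j - mu_x - mu_y) ** 4) * P).sum()),
        "CS": float((((i + j - mu_x - mu_y) ** 3) * P).sum()),
        "DIS": float((np.abs(i - j) * P).sum()),
        "ASM": float((P ** 2).sum()),
        "ENT": hxy,
        "IDM": float((P / (1.0 + (i - j) ** 2)).sum()),
        "MP": float(P.max()),
        "SOS": float((((i - mu_x) ** 2) * P).sum()),
        "SA": float(sa),
        "SV": float(((np.arange(2 * L - 1) - sa) ** 2 * p_sum).sum()),
        "SE": ent(p_sum),
        "DV": float(((np.arange(L) - mu_d) ** 2 * p_diff).sum()),
        "DE": ent(p_diff),
        "IMC": 0.0 if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy),
        "IDN": float((P / (1.0 + np.abs(i - j) / L)).sum()),
        "IDMN": float((P / (1.0 + (i - j) ** 2 / L ** 2)).sum()),
    }


class TestHistogram:
    def test_constant_degenerate(self):
        f = histogram_features(_roi(np.full((4, 4), 9), n_levels=256))
        assert f["Variance"] == 0 and f["Skewness"] == 0 and f["Kurtosis"] == 0

    def test_symmetric_two_point(self):
        grid = np.zeros((4, 4), int)
        grid[:2] = 255
        f = histogram_features(_roi(grid, n_levels=256))
        assert f["Mean"] == pytest.approx(127.5)
        assert f["Skewness"] == pytest.approx(0)
        # two-point symmetric distribution: variance = (255/2)^2
        assert f["Variance"] == pytest.approx(255 ** 2 / 4)

    def test_single_outlier_mean(self):
        grid = np.array([[0, 0], [0, 255]])
        f = histogram_features(_roi(grid, n_levels=256))
        assert f["Mean"] == pytest.approx(63.75)


class TestGLCM:
    def test_constant_2x2_single_cell(self):
        m = glcm(_roi(np.full((2, 2), 5), n_levels=8), (0, 1))
        assert m.p.sum() == pytest.approx(1)
        assert len(m.p) == 1 and m.i[0] == 5 and m.j[0] == 5

    def test_checkerboard_hand_count(self):
        # 12 horizontal pairs on a 4x4 board, every pair is (0,1) or (1,0)
        q = make_fixture("checkerboard", (4, 4), levels=2)
        m = glcm(q, (0, 1), symmetric=True).dense()
        assert m[0, 1] == pytest.approx(0.5)
        assert m[1, 0] == pytest.approx(0.5)
        assert m[0, 0] == m[1, 1] == 0

    def test_normalization(self, rng):
        grid = rng.integers(0, 8, (6, 6))
        m = glcm(_roi(grid, n_levels=8), (-2, 1))
        assert m.p.sum() == pytest.approx(1)

    def test_mask_boundary_pairs_excluded(self):
        grid = np.array([[1, 2, 3, 4]] * 2)
        mask = np.array([[True, True, False, True]] * 2)
        m = glcm(_roi(grid, mask, n_levels=8), (0, 1), symmetric=False)
        # only the (1,2) pair per row survives; (2,3) and (3,4) cross the gap
        assert m.dense()[1, 2] == pytest.approx(1.0)

    def test_empty_pairs_error(self):
        from texomri.texture import EmptyPairsError

        q = _roi(np.zeros((3, 3), int), n_levels=4)
        with pytest.raises(EmptyPairsError):
            glcm(q, (0, 5))

    def test_constant_image_degeneracies(self):
        f = glcm_features(
            _roi(np.full((8, 8), 3), n_levels=8), GLCMConfig(distances=(1, 2))
        )
        for name, val in f.items():
            stat = name.split()[-1]
            if stat in ("CON", "DIS"):
                assert val == 0
            elif stat in ("ASM", "IDM", "MP"):
                assert val == pytest.approx(1)
            elif stat == "ENT":
                assert val == pytest.approx(0)

    def test_checkerboard_contrast_and_asm(self):
        q = make_fixture("checkerboard", (4, 4), levels=2)
        f = glcm_features(q, GLCMConfig(distances=(1,)))
        assert f["S(0,1) CON"] == pytest.approx(1.0)
        assert f["S(0,1) ASM"] == pytest.approx(0.5)

    def test_all_features_match_brute_force_oracle(self, rng):
        cfg = GLCMConfig()
        for trial in range(20):
            grid = rng.integers(0, 8, (6, 6))
            mask = np.ones((6, 6), bool)
            if trial % 4 == 0:  # some trials with ragged masks
                mask = rng.random((6, 6)) < 0.8
                mask[0, 0] = mask[-1, -1] = True
            q = _roi(grid, mask, n_levels=8)
            try:
                feats = glcm_features(q, cfg)
            except ValueError:
                continue  # mask too thin for some offset: skip trial
            for d in cfg.distances:
                for dr, dc in cfg.offsets(d):
                    P = glcm_oracle(grid, mask, (dr, dc), 8)
                    expected = glcm_stats_oracle(P)
                    for name in GLCM_FEATURE_NAMES:
                        assert feats[f"S({dr},{dc}) {name}"] == pytest.approx(
                            expected[name], rel=1e-10, abs=1e-12
                        ), f"{name} offset ({dr},{dc})"

    def test_directional_mean_is_arithmetic_mean(self, rng):
        grid = rng.integers(0, 8, (8, 8))
        f = glcm_features(_roi(grid, n_levels=8), GLCMConfig(distances=(2,)))
        for name in GLCM_FEATURE_NAMES:
            dirs = [f[f"S({dr},{dc}) {name}"] for dr, dc in GLCMConfig().offsets(2)]
            assert f[f"S(2,mean) {name}"] == pytest.approx(np.mean(dirs))

    def test_rotation_permutes_directions(self, rng):
        grid = rng.integers(0, 8, (8, 8))
        rot = np.rot90(grid)
        f = glcm_features(_roi(grid, n_levels=8), GLCMConfig(distances=(1,)))
        g = glcm_features(_roi(rot, n_levels=8), GLCMConfig(distances=(1,)))
        # rot90 maps offset (dr,dc) -> (-dc,dr); symmetric GLCMs identify
        # (0,-1) with (0,1) and (1,-1) with (-1,1)
        mapping = {
            "S(0,1)": "S(-1,0)",
            "S(-1,0)": "S(0,1)",
            "S(-1,1)": "S(-1,-1)",
            "S(-1,-1)": "S(-1,1)",
        }
        for src, dst in mapping.items():
            for name in GLCM_FEATURE_NAMES:
                assert f[f"{src} {name}"] == pytest.approx(
                    g[f"{dst} {name}"], rel=1e-10
                )


class TestGRLM:
    def test_single_row_run(self):
        grid = np.zeros((2, 7), int)
        grid[0] = 4
        mask = np.zeros((2, 7), bool)
        mask[0] = True
        f = grlm_features(_roi(grid, mask, n_levels=8), GRLMConfig(directions=(0,)))
        assert f["LRE_0"] == pytest.approx(49)
        assert f["SRE_0"] == pytest.approx(1 / 49)
        assert f["FIR_0"] == pytest.approx(1 / 7)  # one run over 7 pixels

    def test_checkerboard_unit_runs(self):
        q = make_fixture("checkerboard", (6, 6), levels=2)
        f = grlm_features(q, GRLMConfig(directions=(0, 90)))
        assert f["SRE_0"] == f["LRE_0"] == pytest.approx(1.0)
        assert f["FIR_0"] == pytest.approx(1.0)

    @pytest.mark.parametrize("direction", [0, 45, 90, 135])
    def test_pixel_conservation(self, rng, direction):
        """sum(count * run_length) over the matrix equals the masked pixel count."""
        from texomri.texture import _run_length_matrix

        for _ in range(25):
            grid = rng.integers(0, 4, (7, 9))
            mask = rng.random((7, 9)) < 0.7
            if not mask.any():
                continue
            q = _roi(grid, mask, n_levels=4)
            R = _run_length_matrix(q, direction)
            lengths = np.arange(1, R.shape[1] + 1)
            assert (R.sum(axis=0) * lengths).sum() == mask.sum()


class TestDWT:
    def test_constant_image_no_detail(self):
        q = make_fixture("constant", (16, 16))
        f = dwt_features(q)
        for w in ("haar", "db2", "sym4"):
            for lvl in range(1, 5):
                for sub in ("HH", "DH", "HD"):
                    assert f[f"{w} {sub}_{lvl}"] == pytest.approx(0, abs=1e-20)
            assert f[f"{w} LL_4"] == pytest.approx(1.0)

    @pytest.mark.parametrize("wavelet", ["haar", "db2", "sym4"])
    def test_parseval_equality(self, rng, wavelet):
        grid = rng.integers(0, 256, (16, 16))
        f = dwt_features(_roi(grid, n_levels=256), DWTConfig(wavelets=(wavelet,)))
        total = f[f"{wavelet} LL_4"] + sum(
            f[f"{wavelet} {sub}_{lvl}"]
            for sub in ("HH", "DH", "HD")
            for lvl in range(1, 5)
        )
        assert total == pytest.approx(1.0, rel=1e-8)

    def test_impulse_level1_haar_by_hand(self):
        """A centered unit impulse: every level-1 haar subband coefficient in
        the impulse's 2x2 block is +-v/2, so each subband carries v^2/4."""
        q = make_fixture("impulse", (16, 16))
        f = dwt_features(q, DWTConfig(wavelets=("haar",)))
        for sub in ("HH", "DH", "HD", "LL"):
            assert f[f"haar {sub}_1"] == pytest.approx(0.25)


class TestAssembly:
    def test_inventory_counts(self):
        names = feature_names()
        assert len(names) == 488
        assert len(set(names)) == 488
        glcm_n = sum(n.startswith("S(") for n in names)
        grlm_n = sum(any(n.startswith(p) for p in (
            "RLN", "GLN", "LRE", "SRE", "FIR", "LGRE", "HGRE",
            "SRLGE", "SRHGE", "LRLGE", "LRHGE")) for n in names)
        dwt_n = sum(n.startswith(("haar", "db2", "sym4")) for n in names)
        assert glcm_n == 380 and grlm_n == 44 and dwt_n == 60
        assert 488 - glcm_n - grlm_n - dwt_n == 4

    def test_extract_features_order_and_determinism(self, rng):
        grid = rng.integers(0, 256, (16, 16))
        q = _roi(grid, n_levels=256)
        f1 = extract_features(q)
        f2 = extract_features(q)
        assert list(f1) == feature_names()
        assert f1 == f2

    def test_extract_all_tags_failing_phase(self):
        good = _roi(np.arange(256).reshape(16, 16) % 256, n_levels=256)
        thin_mask = np.zeros((16, 16), bool)
        thin_mask[0, :2] = True  # too thin for distance-4 vertical offsets
        bad = _roi(np.arange(256).reshape(16, 16) % 8, thin_mask, n_levels=8)
        with pytest.raises(ValueError, match=r"phase=post"):
            extract_all(good, bad, good)
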