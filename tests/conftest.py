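import numpy as np
import pytest
import trimesh

import osteomorph as om


@pytest.fixture(scope="session")
def circle_1024():
    t = np.linspace(0, 2 * np.pi, 1024, endpoint=False)
    return np.column_stack([np.cos(t), np.sin(t)])


@pytest.fixture(scope="session")
def ellipse_1024():
    t = np.linspace(0, 2 * np.pi, 1024, endpoint=False)
    return np.column_stack([2 * np.cos(t), np.sin(t)])


@pytest.fixture(scope="session")
def reference_mesh():
    """Deterministic, unposed synthetic bone (~2000 faces)."""
    mesh, _ = om.make_mesh(om.ShapeEffectSpec(), 2000, seed=1, random_pose=False)
    return mesh


@pytest.fixture(scope="session")
def small_design():
    import pandas as pd

    rows = []
    for i, (sp, strat) in enumerate(
            [("spA", "transfer"), ("spB", "transfer"),
             ("spC", "pelvic"), ("spD", "pelvic")]):
        for sex in ("female", "male"):
            for k in range(3):
                rows.append(dict(specimen_id=f"{sp}_{sex[0]}{k}", species=sp,
                                 sex=sex, strategy=strat,
                                 standard_length=30.0 + i + k, side="right"))
    return om.DesignTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_tree():
    from osteomorph.pipeline import read_tree_from_string
    return read_tree_from_string(
        "((spA:0.5,spB:0.5):0.5,(spC:0.5,spD:0.5):0.5);")


def brute_hausdorff(points: np.ndarray, mesh: trimesh.Trimesh) -> np.ndarray:
    """Exact point-to-surface distances by brute force over all triangles.

    Independent oracle: clamped barycentric projection refined with exact
    edge projections, no spatial index.
    """
    tri = mesh.triangles
    A, B, C = tri[:, 0], tri[:, 1], tri[:, 2]
    AB, AC = B - A, C - A
    out = np.empty(len(points))
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, p in enumerate(points):
            AP = p - A
            d1 = (AB * AP).sum(1)
            d2 = (AC * AP).sum(1)
            d00 = (AB * AB).sum(1)
            d01 = (AB * AC).sum(1)
            d11 = (AC * AC).sum(1)
            denom = d00 * d11 - d01 * d01
            v = np.clip(np.where(denom > 0, (d11 * d1 - d01 * d2) / denom, 0), 0, 1)
            w = np.clip(np.where(denom > 0, (d00 * d2 - d01 * d1) / denom, 0), 0, 1)
            s = v + w
            scale = np.where(s > 1, 1 / s, 1.0)
            v, w = v * scale, w * scale
            P = A + v[:, None] * AB + w[:, None] * AC
            d = np.linalg.norm(P - p, axis=1)
            for E0, EV in ((A, AB), (A, AC), (B, C - B)):
                L2 = (EV * EV).sum(1)
                t = np.clip(np.where(L2 > 0, ((p - E0) * EV).sum(1) / L2, 0), 0, 1)
                d = np.minimum(d, np.linalg.norm(E0 + t[:, None] * EV - p, axis=1))
            out[i] = d.min()
    return out
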