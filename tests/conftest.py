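import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numerical_gradient(fn, arr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar fn() w.r.t. arr (in place)."""
    grad = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        arr[i] += eps
        fp = float(fn().data)
        arr[i] -= 2 * eps
        fm = float(fn().data)
        arr[i] += eps
        grad[i] = (fp - fm) / (2 * eps)
    return grad


@pytest.fixture
def gradcheck():
    def check(fn, tensors, tol=1e-6):
        for t in tensors:
            t.zero_grad()
        out = fn()
        out.backward()
        for t in tensors:
            num = numerical_gradient(fn, t.data)
            scale = max(1.0, float(np.abs(num).max()))
            assert np.abs(t.grad - num).max() / scale < tol, \
                f"gradient mismatch (analytic vs numeric) for tensor {t.shape}"
    return check


def make_alphapose_records(n_frames: int, n_joints: int = 17, with_face: bool = False,
                           rng=None, start: int = 0):
    """Synthesize an AlphaPose-style COCO-results JSON payload."""
    rng = rng or np.random.default_rng(0)
    records = []
    for t in range(start, start + n_frames):
        kps = []
        for _ in range(n_joints):
            kps += [float(rng.uniform(0, 1280)), float(rng.uniform(0, 720)),
                    float(rng.uniform(0.5, 1.0))]
        rec = {"image_id": f"{t}.jpg", "category_id": 1, "keypoints": kps,
               "score": 2.5}
        if with_face:
            fkps = []
            for _ in range(68):
                fkps += [float(rng.uniform(500, 800)), float(rng.uniform(100, 300)),
                         float(rng.uniform(0.5, 1.0))]
            rec["face_keypoints"] = fkps
        records.append(rec)
    return records
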