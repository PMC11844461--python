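import numpy as np
import pytest

from lipstereo import default_rig


@pytest.fixture(scope="session")
def rig():
    """Study-geometry zero-distortion rig shared across tests."""
    return default_rig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def write_session(out_dir, scene, jitter=None, stagger_samples=None, seed=0):
    """Persist a synthetic scene as a full on-disk session; returns paths."""
    from lipstereo import io as lio
    from lipstereo.synth import render_audio, render_tracks

    out_dir.mkdir(parents=True, exist_ok=True)
    left, right = render_tracks(scene, jitter, jitter, seed=seed)
    paths = {
        "tracks_left": out_dir / "tracks_left.csv",
        "tracks_right": out_dir / "tracks_right.csv",
        "calibration": out_dir / "calibration.json",
        "reference": out_dir / "reference.csv",
    }
    lio.write_track_csv(left, paths["tracks_left"])
    lio.write_track_csv(right, paths["tracks_right"])
    lio.write_calibration(scene.rig, paths["calibration"])
    lio.write_aperture_csv(scene.reference, paths["reference"])
    if stagger_samples is not None:
        al, ar = render_audio(scene, stagger_samples=stagger_samples, seed=seed)
        paths["audio_left"] = out_dir / "audio_left.wav"
        paths["audio_right"] = out_dir / "audio_right.wav"
        lio.write_wav(al, paths["audio_left"])
        lio.write_wav(ar, paths["audio_right"])
    return {k: str(v) for k, v in paths.items()}


def random_rig(rng, distortion=True):
    """A random but physically plausible stereo rig.

    Focal length, principal point, a small distortion (optional) and a right
    camera at a random baseline, toed in toward a point near the working
    volume.
    """
    from lipstereo.geometry import CameraModel, StereoRig

    f = rng.uniform(2000.0, 4000.0)
    cx = 2656.0 + rng.uniform(-50, 50)
    cy = 1494.0 + rng.uniform(-50, 50)
    if distortion:
        dist = (
            rng.uniform(-0.15, 0.15),
            rng.uniform(-0.03, 0.03),
            rng.uniform(-0.002, 0.002),
            rng.uniform(-0.002, 0.002),
        )
    else:
        dist = (0.0, 0.0, 0.0, 0.0)
    left = CameraModel(fx=f, fy=f * rng.uniform(0.98, 1.02), cx=cx, cy=cy, dist=dist)

    baseline = rng.uniform(300.0, 900.0)
    center = np.array([baseline, rng.uniform(-50, 50), rng.uniform(-50, 50)])
    target = np.array([rng.uniform(-50, 350), rng.uniform(-50, 50), 800.0])
    z = target - center
    z /= np.linalg.norm(z)
    x = np.cross([0.0, 1.0, 0.0], z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    right = CameraModel(
        fx=f, fy=f, cx=cx, cy=cy, dist=dist, R=R, t=-R @ center
    )
    return StereoRig(left=left, right=right)
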