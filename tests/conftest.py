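import numpy as np
import pytest

from turflow import CardiacWaveform, CineLoop, FlowConfig, VectorFrame


@pytest.fixture
def small_config() -> FlowConfig:
    """A cheap configuration whose loop spans exactly one cardiac cycle
    (50 frames at 100 Hz / 120 bpm) on a coarser 0.2 mm grid."""
    return FlowConfig(frame_rate=100.0, duration=0.5, grid_spacing=0.2, seed=123)


@pytest.fixture
def waveform() -> CardiacWaveform:
    return CardiacWaveform()


@pytest.fixture
def uniform_frame() -> VectorFrame:
    """A 61 x 41 grid (0.1 mm pitch) with uniform axial flow vx=10 cm/s."""
    x = np.arange(61) * 0.1
    y = np.arange(41) * 0.1
    vx = np.full((y.size, x.size), 10.0)
    vy = np.zeros_like(vx)
    return VectorFrame(x=x, y=y, vx=vx, vy=vy)


def random_loop(seed: int, n_frames: int = 6, nx: int = 25, ny: int = 15) -> CineLoop:
    """A loop of i.i.d. Gaussian velocity fields for exercising the Tur
    machinery independently of the flow generator."""
    rng = np.random.default_rng(seed)
    x = np.arange(nx) * 0.1
    y = np.arange(ny) * 0.1
    return CineLoop(
        x=x, y=y,
        vx=rng.normal(size=(n_frames, ny, nx)),
        vy=rng.normal(size=(n_frames, ny, nx)),
        frame_rate=100.0, heart_rate=120.0,
        vessel_diameter=1.0, lumen_center_y=0.7,
    )
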