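import pytest

from loopstate import GeneratorConfig, default_loop_design, generate_dataset


@pytest.fixture(scope="session")
def design():
    return default_loop_design()


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free, defect-free, zero-dye-bias data: exact round trips."""
    cfg = GeneratorConfig(
        n_steady_up=8, n_steady_down=8, n_cumulative_up=4, n_cumulative_down=4,
        n_flat=16, noise_sd_range=(0.0, 0.0), dye_bias_range=(0.0, 0.0),
        defective_spot_rate=0.0, print_tip_blocks=2, seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Moderate noise, dye bias and defects for behavioural tests."""
    cfg = GeneratorConfig(
        n_steady_up=20, n_steady_down=20, n_cumulative_up=10, n_cumulative_down=10,
        n_flat=40, defective_spot_rate=0.2, print_tip_blocks=2, seed=5,
    )
    return generate_dataset(cfg)
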