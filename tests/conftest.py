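import pytest

from wsiweak.synthdata import SyntheticSlideSpec, generate_slide


@pytest.fixture(scope="session")
def adc_slide():
    """One deterministic ADC slide with a mid-sized lesion."""
    return generate_slide(
        SyntheticSlideSpec(label="ADC", lesion_fraction=0.05,
                           tissue_fraction=0.6, width_px=512, height_px=512,
                           seed=7)
    )


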