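import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def tiny_main_model():
    """A small 4-class segmentation net trained briefly on synthetic renders.

    Shared across the pipeline and acceptance tests; training takes about a
    minute on one CPU.
    """
    from ecgdigitize.pipeline import training_batches
    from ecgdigitize.segnet import TrainConfig, UNet, UNetConfig, train
    model = UNet(UNetConfig(encoder_widths=(8, 16, 32), seed=7))
    cfg = TrainConfig(batch_size=4, patch_px=96, lr_init=0.008,
                      lr_final=0.0008, schedule_batches=300, seed=0)
    train(model, training_batches(300, batch_size=4, crop_px=96, dpi=100,
                                  seed=0), cfg)
    return model


@pytest.fixture(scope="session")
def clean_render_100dpi():
    """A clean, unwarped 3x4+rhythm render at 100 dpi with its truth."""
    from ecgdigitize.synthgen import RenderConfig, render_paper, simulate_ecg
    sig = simulate_ecg(12, 10.0, 1000.0, seed=555)
    sample = render_paper(sig, RenderConfig(dpi=100, seed=555))
    return sample


@pytest.fixture(scope="session")
def oracle_roundtrip_record():
    """Trace extraction run on ground-truth masks of a clean 600-dpi scan.

    Returns (truth_record, reconstructed_record).
    """
    from ecgdigitize.gridscale import Calibration
    from ecgdigitize.layout import get_template
    from ecgdigitize.synthgen import RenderConfig, render_paper, simulate_ecg
    from ecgdigitize.trace import (ECGRecord, assemble_record,
                                   extract_lead_traces)
    sig = simulate_ecg(12, 10.0, 1000.0, {"noise_mv": 0.0}, seed=11)
    cfg = RenderConfig(dpi=600, speed_mm_per_s=50.0, seed=3)
    sample = render_paper(sig, cfg)
    cal = Calibration(*sample.calibration_truth, 50.0, 10.0)
    template = get_template(cfg.layout_name)
    traces = extract_lead_traces(
        (sample.class_mask == 2).astype(np.float32), template, cal)
    rec = assemble_record(traces, template, cal, 1000.0)
    truth = ECGRecord(list(sig.lead_names), sig.samples, 1000.0)
    return truth, rec
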