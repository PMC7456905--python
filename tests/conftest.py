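import numpy as np
import pytest

import medcoder as mc


@pytest.fixture(scope="session")
def small_world():
    """A tiny synthetic world shared by fast tests: 8 codes, 60 records."""
    kg = mc.generate_ontology(8, aux_per_class=5, seed=11)
    spec = mc.GeneratorSpec(
        n_records=60, n_codes=8, codes_per_record=(1, 3), note_length=(30, 60), seed=11
    )
    records, gt = mc.generate_corpus(spec, kg)
    vocab = mc.build_vocabulary([mc.tokenize(r.text) for r in records], min_count=1)
    codes = mc.select_top_codes(records, 8)
    encoded = mc.encode_corpus(records, vocab, codes, max_len=80)
    return {
        "kg": kg, "spec": spec, "records": records, "gt": gt,
        "vocab": vocab, "codes": codes, "encoded": encoded,
    }


@pytest.fixture
def tiny_state():
    """A minimal model for fast forward/backward tests."""
    rng = np.random.default_rng(7)
    cfg = mc.ModelConfig(
        vocab_size=12, n_labels=3, d=6, d_g=4, d_f=3,
        kernel_sizes=(2, 3), pool=2, dropout=0.0, max_len=10,
    )
    y_g = rng.standard_normal((3, 4))
    return mc.ModelState.init(cfg, y_g, seed=7)
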