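import pytest

import dims2decon as d


@pytest.fixture(scope="session")
def noiseless_run():
    """Noiseless two-isobar simulation (Δm/z 0.048) deconvoluted end-to-end."""
    cfg = d.two_isobar_preset(0.048, n_shared=0)
    series, truth = d.simulate_series(cfg)
    refs = {r.compound_id: r for r in d.reference_spectra(cfg)}
    result = d.deconvolute(
        series, cfg.blank_peaks, dict(truth.precursor_mzs), references=refs
    )
    return cfg, series, truth, refs, result
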