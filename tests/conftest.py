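import numpy as np
import pytest

from shademir.rnautil import RNA_BASES


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def random_rna(rng, length: int) -> str:
    return "".join(rng.choice(list(RNA_BASES), size=length))


def null_calibration_trial(rng, n_shuffles: int = 60) -> float | None:
    """One null trial for permutation p-value calibration.

    A random miRNA is scanned against a random transcript carrying a random
    sparse degradome profile; the observed hit is the best-scoring site
    whose expected cleavage position is occupied (the same selection rule
    the shuffles face), and its permutation p-value is returned.  None when
    no window has an occupied cleavage position.
    """
    import numpy as np

    from shademir.degradome import DegradomeProfile, coincidence_filter, site_pvalue
    from shademir.targets import align_duplex, gapless_scores

    mir = random_rna(rng, 21)
    transcript = random_rna(rng, 300)
    occupied = rng.choice(np.arange(1, len(transcript) + 1), size=30, replace=False)
    profile = DegradomeProfile(
        "tx", len(transcript), {int(p): 1 for p in occupied}
    )
    scores = gapless_scores(mir, transcript)
    # gapless window at offset o has its 10th-nucleotide position at o + 12
    order = np.argsort(scores, kind="stable")
    for o in order:
        if profile.count_at(int(o) + 12) < 1:
            continue
        aln = align_duplex(
            mir, transcript[o : o + 21], transcript_id="tx",
            t_start=int(o) + 1, enforce_bounds=False,
        )
        hit = coincidence_filter(aln, profile)
        if hit is None:
            continue
        return site_pvalue(
            hit, profile, mir, transcript,
            n_shuffles=n_shuffles, seed=int(rng.integers(2**31)),
        )
    return None
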