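"""Deterministic seed lineage.

A single experiment master seed derives every per-run / per-epoch substream as
``master * 10**6 + run * 10**3 + epoch`` (mod 2**31 so derived seeds stay in
int32 range).  Epoch slots 1..998 are real epochs; slot 999 is reserved for the
per-run semantic permutation, and run slot 999 for the fold plan.
"""

_MOD = 2**31


def run_epoch_seed(master: int, run: int, epoch: int) -> int:
    return (master * 1_000_000 + run * 1_000 + epoch) % _MOD


def fold_seed(master: int) -> int:
    return run_epoch_seed(master, 999, 999)


def permutation_seed(master: int, run: int) -> int:
    return run_epoch_seed(master, run, 999)
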