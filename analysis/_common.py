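"""Shared paths and the world loader for the numbered analysis scripts."""

from pathlib import Path

from ferronet.pipeline import make_synthetic_world

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
WORLD = ROOT / "scratch" / "world"
SEED = 20130603  # study publication date, used as the default world seed


def ensure_world() -> Path:
    """Generate the synthetic study once; it is deterministic in SEED."""
    if not (WORLD / "truth.json").exists():
        make_synthetic_world(WORLD, seed=SEED)
    RESULTS.mkdir(exist_ok=True)
    return WORLD
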