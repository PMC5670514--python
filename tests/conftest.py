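import itertools

import pytest

from clusterworm.engine import Engine, EngineConfig

_ids = itertools.count()


@pytest.fixture
def make_engine(tmp_path):
    """Factory for engines whose spill dirs live under the test's tmp dir."""
    engines = []

    def _make(n_workers=1, pagesize=1 << 30, **kw):
        eng = Engine(EngineConfig(
            n_workers=n_workers, pagesize=pagesize,
            spill_dir=tmp_path / f"spill{next(_ids)}", **kw))
        engines.append(eng)
        return eng

    yield _make
    for eng in engines:
        eng.close()
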