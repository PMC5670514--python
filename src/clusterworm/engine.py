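"""Map/collate/reduce machinery over partitioned key/value stores.

The engine mirrors the object model of distributed MapReduce libraries used
in HPC bioinformatics: data lives in key/value (KV) and key/multivalue (KMV)
stores split into hash-addressed partitions, and a pipeline alternates three
operations:

``map``
    emit new KV pairs from an input sequence (or an existing KV store),
    each pair routed to the partition owning its key;
``collate``
    group all values sharing a key into one KMV pair on the owning
    partition (the shuffle);
``reduce``
    turn each KMV pair into zero or more new KV pairs.

Partitions are *logical* workers processed sequentially; the hash routing
contract is what a distributed backend would have to preserve.  When a
partition's in-memory pairs exceed ``pagesize`` bytes, full pages are
spilled to length-prefixed binary temp files and transparently read back,
so stores larger than memory behave identically to in-memory stores
(out-of-core processing).

Key ownership uses CRC-32 (IEEE 802.3 polynomial 0x04C11DB7, as implemented
by :func:`zlib.crc32`): a fixed, published, seed-independent 32-bit hash, so
partition assignment is reproducible across runs and platforms.  Value
order inside a KMV pair is unspecified; reducers must be order-insensitive.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import shutil
import struct
import tempfile
from dataclasses import dataclass
from operator import itemgetter
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

from .errors import ConsistencyError, EngineError

logger = logging.getLogger(__name__)

__all__ = [
    "EngineConfig",
    "EngineCounters",
    "Engine",
    "KVStore",
    "KMVStore",
    "partition_owner",
]

_LEN = struct.Struct("<I")

DEFAULT_PAGESIZE = 1 << 30  # 1 GB


def partition_owner(key: bytes, n_workers: int) -> int:
    """Return the logical partition that owns ``key``.

    ``crc32(key) mod n_workers`` — stable across runs and platforms.
    """
    if n_workers < 1:
        raise ValueError(f"n_workers must be >= 1, got {n_workers}")
    from zlib import crc32

    return crc32(key) % n_workers


def _as_bytes(x: bytes | str | int) -> bytes:
    if isinstance(x, bytes):
        return x
    if isinstance(x, str):
        return x.encode("utf-8")
    if isinstance(x, int):
        return str(x).encode("ascii")
    raise TypeError(f"cannot use {type(x).__name__} as key/value")


@dataclass
class EngineConfig:
    """Tunables for the engine: logical worker count, per-partition memory
    budget (bytes) above which pages spill to disk, spill directory and
    whether temp files are kept for inspection."""

    n_workers: int = 1
    pagesize: int = DEFAULT_PAGESIZE
    spill_dir: str | Path | None = None
    seed: int = 0
    keep_temp: bool = False

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.pagesize <= 0:
            raise ValueError("pagesize must be > 0")


@dataclass
class EngineCounters:
    pairs_emitted: int = 0
    bytes_spilled: int = 0
    pages_written: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "pairs_emitted": self.pairs_emitted,
            "bytes_spilled": self.bytes_spilled,
            "pages_written": self.pages_written,
        }


class _Partition:
    """One logical worker's slice of a store.

    Holds pairs in memory up to ``pagesize`` bytes; overflow pages are
    written as length-prefixed records to temp files under ``spill_dir``.
    """

    def __init__(self, index: int, pagesize: int, spill_dir: Path,
                 counters: EngineCounters, page_ids: Iterator[int]) -> None:
        self.index = index
        self.pagesize = pagesize
        self.spill_dir = spill_dir
        self.counters = counters
        self._page_ids = page_ids
        self.pairs: list[tuple[bytes, bytes]] = []
        self.mem_bytes = 0
        self.spill_files: list[Path] = []
        self.n_pairs = 0

    def add(self, key: bytes, value: bytes) -> None:
        self.pairs.append((key, value))
        self.n_pairs += 1
        self.mem_bytes += len(key) + len(value) + 8
        if self.mem_bytes >= self.pagesize:
            self._spill_page()

    def _spill_page(self) -> None:
        path = self.spill_dir / f"part{self.index}-page{next(self._page_ids)}.kv"
        n = 0
        try:
            with open(path, "wb") as fh:
                for k, v in self.pairs:
                    fh.write(_LEN.pack(len(k)))
                    fh.write(k)
                    fh.write(_LEN.pack(len(v)))
                    fh.write(v)
                    n += len(k) + len(v) + 8
        except OSError as exc:
            raise EngineError(f"failed to spill page to {path}: {exc}") from exc
        self.spill_files.append(path)
        self.counters.bytes_spilled += n
        self.counters.pages_written += 1
        self.pairs = []
        self.mem_bytes = 0

    @property
    def spilled(self) -> bool:
        return bool(self.spill_files)

    def _read_page(self, path: Path) -> list[tuple[bytes, bytes]]:
        out = []
        try:
            with open(path, "rb") as fh:
                data = fh.read()
        except OSError as exc:
            raise EngineError(f"failed to read spill page {path}: {exc}") from exc
        off = 0
        n = len(data)
        while off < n:
            (lk,) = _LEN.unpack_from(data, off)
            off += 4
            k = data[off:off + lk]
            off += lk
            (lv,) = _LEN.unpack_from(data, off)
            off += 4
            v = data[off:off + lv]
            off += lv
            out.append((k, v))
        return out

    def iter_pairs(self) -> Iterator[tuple[bytes, bytes]]:
        for path in self.spill_files:
            yield from self._read_page(path)
        yield from self.pairs

    def sorted_runs(self) -> list[Iterator[tuple[bytes, bytes]]]:
        """Key-sorted runs (one per page plus the memory residue) for an
        external merge; each run fits within one pagesize."""
        runs: list[Iterator[tuple[bytes, bytes]]] = []
        for path in self.spill_files:
            runs.append(iter(sorted(self._read_page(path), key=itemgetter(0))))
        if self.pairs:
            runs.append(iter(sorted(self.pairs, key=itemgetter(0))))
        return runs

    def discard(self, keep_temp: bool) -> None:
        if not keep_temp:
            for path in self.spill_files:
                path.unlink(missing_ok=True)
        self.spill_files = []
        self.pairs = []
        self.mem_bytes = 0


class KVStore:
    """Partitioned collection of key/value pairs.

    Every pair resides in the partition given by :func:`partition_owner`;
    partitions spill to disk independently once they exceed ``pagesize``.
    """

    def __init__(self, engine: "Engine") -> None:
        self.engine = engine
        self.partitions = [
            _Partition(i, engine.config.pagesize, engine.spill_dir,
                       engine.counters, engine._page_ids)
            for i in range(engine.config.n_workers)
        ]

    def add(self, key: bytes | str | int, value: bytes | str | int = b"") -> None:
        k = _as_bytes(key)
        if not k:
            raise ValueError("keys must be non-empty")
        v = _as_bytes(value)
        self.partitions[partition_owner(k, len(self.partitions))].add(k, v)
        self.engine.counters.pairs_emitted += 1

    def __len__(self) -> int:
        return sum(p.n_pairs for p in self.partitions)

    def iter_pairs(self) -> Iterator[tuple[bytes, bytes]]:
        for p in self.partitions:
            yield from p.iter_pairs()

    def sorted_pairs(self) -> list[tuple[bytes, bytes]]:
        """All pairs as a sorted list — the canonical multiset view used to
        compare runs across worker counts and pagesizes."""
        return sorted(self.iter_pairs())

    def close(self) -> None:
        for p in self.partitions:
            p.discard(self.engine.config.keep_temp)


class KMVStore:
    """Partitioned collection of key → [values] groups (keys globally
    unique, each on exactly one partition).  Groups are stored serialized,
    reusing the KV spill machinery with the value list packed into one
    record."""

    def __init__(self, engine: "Engine") -> None:
        self.engine = engine
        self.partitions = [
            _Partition(i, engine.config.pagesize, engine.spill_dir,
                       engine.counters, engine._page_ids)
            for i in range(engine.config.n_workers)
        ]

    @staticmethod
    def _pack(values: Sequence[bytes]) -> bytes:
        chunks = [_LEN.pack(len(values))]
        for v in values:
            chunks.append(_LEN.pack(len(v)))
            chunks.append(v)
        return b"".join(chunks)

    @staticmethod
    def _unpack(blob: bytes) -> list[bytes]:
        (n,) = _LEN.unpack_from(blob, 0)
        off = 4
        out = []
        for _ in range(n):
            (lv,) = _LEN.unpack_from(blob, off)
            off += 4
            out.append(blob[off:off + lv])
            off += lv
        return out

    def add_group(self, key: bytes, values: Sequence[bytes]) -> None:
        if not values:
            raise ValueError("KMV groups must have at least one value")
        self.partitions[partition_owner(key, len(self.partitions))].add(
            key, self._pack(values))

    def __len__(self) -> int:
        return sum(p.n_pairs for p in self.partitions)

    def iter_groups(self) -> Iterator[tuple[bytes, list[bytes]]]:
        for p in self.partitions:
            for k, blob in p.iter_pairs():
                yield k, self._unpack(blob)

    def close(self) -> None:
        for p in self.partitions:
            p.discard(self.engine.config.keep_temp)


MapFn = Callable[..., Iterable[tuple[bytes | str | int, bytes | str | int]]]
ReduceFn = Callable[[bytes, list[bytes]], Iterable[tuple[bytes | str | int, bytes | str | int]]]


class Engine:
    """Sequential driver for map/collate/reduce over partitioned stores.

    Usable as a context manager; temp spill files live under a private
    directory that is removed on close unless ``keep_temp`` is set.
    """

    def __init__(self, config: EngineConfig | None = None) -> None:
        self.config = config or EngineConfig()
        self.counters = EngineCounters()
        self._page_ids = itertools.count()
        if self.config.spill_dir is None:
            self._own_dir = True
            self.spill_dir = Path(tempfile.mkdtemp(prefix="clusterworm-spill-"))
        else:
            self._own_dir = False
            self.spill_dir = Path(self.config.spill_dir)
            self.spill_dir.mkdir(parents=True, exist_ok=True)

    # -- lifecycle ---------------------------------------------------------

    def __enter__(self) -> "Engine":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def close(self) -> None:
        if self._own_dir and not self.config.keep_temp:
            shutil.rmtree(self.spill_dir, ignore_errors=True)

    # -- operations --------------------------------------------------------

    def map(self, items: Iterable | KVStore, map_fn: MapFn,
            consume: bool = False) -> KVStore:
        """Emit pairs from ``items`` (any iterable, or an existing KVStore
        whose (key, value) tuples become the items) into a new store.

        ``map_fn(item)`` returns an iterable of (key, value) pairs; it must
        be pure.  Callback exceptions propagate with the item attached.
        """
        out = KVStore(self)
        source: Iterable
        src_store: KVStore | None = None
        if isinstance(items, KVStore):
            src_store = items
            source = items.iter_pairs()
        else:
            source = items
        for item in source:
            try:
                emitted = map_fn(item)
            except ConsistencyError:
                raise
            except Exception as exc:
                raise EngineError(
                    f"map callback failed on item {item!r}: {exc}") from exc
            if emitted:
                for k, v in emitted:
                    out.add(k, v)
        if consume and src_store is not None:
            src_store.close()
        return out

    def collate(self, kv: KVStore, consume: bool = True) -> KMVStore:
        """Group the store's pairs by key: one KMV group per distinct key,
        the (key, value) multiset preserved exactly.

        In-memory partitions group with a hash map; spilled partitions use
        an external sort-and-merge over page-sized sorted runs, so the
        result is identical whether or not any partition paged to disk.
        """
        out = KMVStore(self)
        for src, dst in zip(kv.partitions, out.partitions):
            if not src.spilled:
                groups: dict[bytes, list[bytes]] = {}
                for k, v in src.pairs:
                    groups.setdefault(k, []).append(v)
                for k, vals in groups.items():
                    dst.add(k, KMVStore._pack(vals))
            else:
                merged = heapq.merge(*src.sorted_runs(), key=itemgetter(0))
                for k, grp in itertools.groupby(merged, key=itemgetter(0)):
                    dst.add(k, KMVStore._pack([v for _, v in grp]))
        if consume:
            kv.close()
        return out

    def reduce(self, kmv: KMVStore, reduce_fn: ReduceFn,
               consume: bool = True) -> KVStore:
        """Apply ``reduce_fn(key, values)`` to every group exactly once,
        collecting the emitted pairs into a new KVStore."""
        out = KVStore(self)
        for part in kmv.partitions:
            for key, blob in part.iter_pairs():
                values = KMVStore._unpack(blob)
                try:
                    emitted = reduce_fn(key, values)
                except ConsistencyError:
                    raise
                except Exception as exc:
                    raise EngineError(
                        f"reduce callback failed on key {key!r}: {exc}") from exc
                if emitted:
                    for k, v in emitted:
                        out.add(k, v)
        if consume:
            kmv.close()
        return out
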