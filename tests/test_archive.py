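"""Archive container: random access, appending, integrity, model binding."""

import copy
import io

import pytest

from prostar.archive import Archive, CompressionParams, detect_file_type
from prostar.coord_codec import LossyParams
from prostar.errors import ArchiveError, ModelMismatch
from prostar.fixtures import FixtureSpec, gen_structure


@pytest.fixture()
def filled(tmp_path, corpus_dir, model):
    arc = tmp_path / "a.psar"
    paths = sorted(corpus_dir.iterdir())
    with Archive.create(arc, model) as ar:
        for p in paths:
            ar.add_bytes(p.name, p.read_bytes())
    return arc, paths


def test_add_list_extract_byte_exact(filled, model):
    arc, paths = filled
    with Archive.open(arc, model) as ar:
        assert ar.names() == [p.name for p in paths]
        for p in paths:
            assert ar.extract(p.name) == p.read_bytes()


def test_listing_shows_types_and_flags(tmp_path, corpus_dir, model):
    arc = tmp_path / "a.psar"
    p = sorted(corpus_dir.glob("*.cif"))[0]
    params = CompressionParams(lossy=LossyParams(m_backbone=80,
                                                 m_sidechain=140))
    with Archive.create(arc, model) as ar:
        ar.add_bytes(p.name, p.read_bytes(), params)
    with Archive.open(arc, model) as ar:
        e = ar.list()[0]
        assert e.file_type == "cif"
        assert (e.lossy_backbone, e.lossy_sidechain) == (80, 140)


def test_append_leaves_existing_bytes_untouched(filled, tmp_path, model):
    arc, paths = filled
    first_entry_end = None
    with Archive.open(arc, model) as ar:
        last = ar.list()[-1]
        first_entry_end = last.offset + last.length
    before = arc.read_bytes()[:first_entry_end]
    extra = tmp_path / "readme.txt"
    extra.write_text("plain text payload\n" * 20)
    with Archive.append(arc, model) as ar:
        ar.add_file(extra)
    after = arc.read_bytes()[:first_entry_end]
    assert after == before
    with Archive.open(arc, model) as ar:
        assert ar.extract("readme.txt") == extra.read_bytes()
        assert len(ar.list()) == len(paths) + 1


def test_append_then_reopen_equals_single_pass(tmp_path, corpus_dir, model):
    paths = sorted(corpus_dir.iterdir())[:6]
    one = tmp_path / "one.psar"
    with Archive.create(one, model) as ar:
        for p in paths:
            ar.add_bytes(p.name, p.read_bytes())
    two = tmp_path / "two.psar"
    with Archive.create(two, model) as ar:
        for p in paths[:3]:
            ar.add_bytes(p.name, p.read_bytes())
    with Archive.append(two, model) as ar:
        for p in paths[3:]:
            ar.add_bytes(p.name, p.read_bytes())
    assert one.read_bytes() == two.read_bytes()


def test_archive_bytes_deterministic(tmp_path, corpus_dir, model):
    paths = sorted(corpus_dir.iterdir())[:6]
    blobs = []
    for run in range(2):
        arc = tmp_path / f"r{run}.psar"
        with Archive.create(arc, model) as ar:
            for p in paths:
                ar.add_bytes(p.name, p.read_bytes())
        blobs.append(arc.read_bytes())
    assert blobs[0] == blobs[1]


def test_duplicate_name_rejected(tmp_path, model):
    with Archive.create(tmp_path / "a.psar", model) as ar:
        ar.add_bytes("x.txt", b"abc")
        with pytest.raises(ArchiveError, match="duplicate"):
            ar.add_bytes("x.txt", b"def")


def test_unknown_type_stored_opaque(tmp_path, model):
    data = b"arbitrary \x00 binary-ish payload" * 10
    arc = tmp_path / "a.psar"
    with Archive.create(arc, model) as ar:
        e = ar.add_bytes("blob.bin", data)
        assert e.file_type == "opaque"
    with Archive.open(arc, model) as ar:
        assert ar.extract("blob.bin") == data


def test_malformed_structures_never_lose_data(tmp_path, model):
    # a broken ATOM line demotes to generic text handling, still byte-exact
    bad = b"ATOM  not a real pdb line\nEND\n"
    # undecodable bytes cannot be parsed at all -> whole-file opaque blob
    binary = b"\xff\xfe not text \x00" * 4
    arc = tmp_path / "a.psar"
    with Archive.create(arc, model) as ar:
        e1 = ar.add_bytes("broken.pdb", bad)
        e2 = ar.add_bytes("binary.pdb", binary)
        assert not e1.opaque_fallback
        assert e2.opaque_fallback and e2.file_type == "opaque"
    with Archive.open(arc, model) as ar:
        assert ar.extract("broken.pdb") == bad
        assert ar.extract("binary.pdb") == binary


def test_missing_entry_and_corrupt_footer(tmp_path, model):
    arc = tmp_path / "a.psar"
    with Archive.create(arc, model) as ar:
        ar.add_bytes("x.txt", b"abc")
    with Archive.open(arc, model) as ar:
        with pytest.raises(ArchiveError, match="no entry"):
            ar.extract("y.txt")
    raw = bytearray(arc.read_bytes())
    raw[-1] ^= 0xFF
    arc.write_bytes(bytes(raw))
    with pytest.raises(ArchiveError):
        Archive.open(arc, model)


def test_payload_corruption_detected(filled, model):
    arc, paths = filled
    raw = bytearray(arc.read_bytes())
    with Archive.open(arc, model) as ar:
        e = ar.list()[0]
    raw[e.offset + e.length // 2] ^= 0xFF
    arc.write_bytes(bytes(raw))
    with Archive.open(arc, model) as ar:
        with pytest.raises(ArchiveError, match="checksum"):
            ar.extract(e.name)


def test_wrong_model_refused_before_output(filled, model):
    arc, paths = filled
    other = copy.deepcopy(model)
    key = next(iter(other.entries))
    other.entries[key].centroid_set.centroids[0][0] += 0.5
    other.invalidate()
    with Archive.open(arc, other) as ar:
        with pytest.raises(ModelMismatch):
            ar.extract(paths[0].name)
        # non-structure entries do not involve the model
        pae_name = next(p.name for p in paths if p.name.endswith(".pae.json"))
        assert ar.extract(pae_name)


class _CountingFile(io.FileIO):
    def __init__(self, *a, **kw):
        super().__init__(*a, **kw)
        self.bytes_read = 0

    def read(self, n=-1):
        data = super().read(n)
        self.bytes_read += len(data)
        return data


def test_listing_and_extraction_touch_few_bytes(tmp_path, model):
    """Listing reads only footer + directory; extracting one entry reads
    only that entry's payload."""
    arc = tmp_path / "many.psar"
    with Archive.create(arc, model) as ar:
        for i in range(200):
            ar.add_bytes(f"f{i:04d}.txt", f"payload {i}\n".encode() * 20)
    raw = arc.read_bytes()
    dir_len = int.from_bytes(raw[-24:-16], "little")

    ar = Archive.open(arc, model)
    counting = _CountingFile(arc, "rb")
    ar._fh.close()
    ar._fh = counting
    ar._read_directory()
    listing_bytes = counting.bytes_read
    assert len(ar.list()) == 200
    # magic + footer + directory, nothing from the payload region
    assert listing_bytes <= dir_len + 32 + 8 + 16

    counting.bytes_read = 0
    mid = ar.list()[100]
    ar.extract(mid.name)
    assert counting.bytes_read <= mid.length + 64
    ar._fh.close()


def test_minimal_mode_keeps_header_and_atom_table(tmp_path, model):
    s = gen_structure(FixtureSpec(n_structures=1, residues_per_chain=10,
                                  seed=4), 0)
    arc = tmp_path / "a.psar"
    params = CompressionParams(lossy=LossyParams(minimal=True))
    with Archive.create(arc, model) as ar:
        e = ar.add_bytes("s.pdb", s.pdb_text.encode(), params)
        assert e.minimal
    with Archive.open(arc, model) as ar:
        got = ar.extract("s.pdb").decode()
    from prostar.formats_io import parse_structure
    secs = parse_structure(s.pdb_text, "pdb")
    want = secs[0].raw_text + "".join(x.raw_text for x in secs
                                      if x.table_kind == "atom")
    assert got == want
    assert "END" not in got


def test_detect_file_type():
    assert detect_file_type("x.pdb", b"") == "pdb"
    assert detect_file_type("x.cif", b"") == "cif"
    assert detect_file_type("x.json",
                            b'{"predicted_aligned_error":[[0]]}') == "pae"
    assert detect_file_type(
        "x.json", b'{"residueNumber":[1],"confidenceScore":[1.0],'
                  b'"confidenceCategory":["H"]}') == "confidence"
    assert detect_file_type("x.json", b"{nope") == "opaque"
    assert detect_file_type("x.dat", b"...") == "opaque"
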