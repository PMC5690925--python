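import datetime

import pytest
from PIL import Image

from cobaltqa import (
    ErrorSpec,
    GridSpec,
    ToleranceConfig,
    default_reference_sources,
    generate_plan,
    inject_error,
    simulate_delivery,
)
from cobaltqa.fileio import (
    ConfigError,
    ParseError,
    load_config,
    load_screen_captures,
    parse_delivery_log,
    parse_plan_overview,
    write_config,
    write_delivery_log,
    write_plan_overview,
)

DATE = datetime.date(2016, 4, 1)


@pytest.mark.parametrize("seed", range(20))
def test_plan_roundtrip_is_identity(seed):
    plan = generate_plan(seed, n_groups=1 + seed % 2, beams_per_group=1 + seed % 3)
    assert parse_plan_overview(write_plan_overview(plan)) == plan


@pytest.mark.parametrize("seed", range(20))
def test_log_roundtrip_is_identity(seed):
    plan = generate_plan(seed)
    record = simulate_delivery(plan, default_reference_sources(), DATE, seed=seed)
    if seed % 3 == 0:  # include interrupted-and-resumed segments
        record = inject_error(
            record,
            ErrorSpec(kind="interruption_split", magnitude=1.0,
                      beam_id=plan.beams[0].beam_id, segment_index=1),
        )
    assert parse_delivery_log(write_delivery_log(record)) == record


def test_minimal_plan_roundtrip():
    plan = generate_plan(1, n_groups=1, beams_per_group=1, segments_per_beam=1)
    assert parse_plan_overview(write_plan_overview(plan)) == plan


class TestParseErrors:
    def test_missing_leaf_pair_cites_segment(self):
        text = write_plan_overview(generate_plan(2))
        lines = text.splitlines()
        drop = next(i for i, ln in enumerate(lines) if ln.startswith("LEAF 7 ="))
        broken = "\n".join(lines[:drop] + lines[drop + 1:])
        with pytest.raises(ParseError, match="29 leaf pairs"):
            parse_plan_overview(broken)

    def test_nonnumeric_value_names_line_and_key(self):
        text = write_plan_overview(generate_plan(2))
        broken = text.replace("GANTRY_DEG = ", "GANTRY_DEG = twelve", 1)
        with pytest.raises(ParseError, match=r"line \d+.*GANTRY_DEG"):
            parse_plan_overview(broken)

    def test_missing_required_key_is_never_defaulted(self):
        text = write_plan_overview(generate_plan(2))
        broken = "\n".join(
            ln for ln in text.splitlines() if not ln.startswith("NOMINAL_DOSE_RATE")
        )
        with pytest.raises(ParseError, match="NOMINAL_DOSE_RATE_GY_MIN"):
            parse_plan_overview(broken)

    def test_unknown_format_version_rejected(self):
        text = write_plan_overview(generate_plan(2))
        with pytest.raises(ParseError, match="FORMAT_VERSION"):
            parse_plan_overview(text.replace("FORMAT_VERSION = 1", "FORMAT_VERSION = 99"))

    def test_missing_source_section_rejected(self):
        record = simulate_delivery(generate_plan(2), default_reference_sources(), DATE)
        text = write_delivery_log(record)
        stripped = []
        skipping = False
        for ln in text.splitlines():
            if ln.strip() == "[SOURCE]":
                skipping = True
            elif ln.startswith("["):
                skipping = False
            if not skipping:
                stripped.append(ln)
        with pytest.raises(ParseError, match="source info absent"):
            parse_delivery_log("\n".join(stripped))

    def test_unknown_key_rejected(self):
        text = write_plan_overview(generate_plan(2))
        broken = text.replace("[PLAN]\n", "[PLAN]\nCOUCH_ANGLE = 5\n", 1)
        with pytest.raises(ParseError, match="COUCH_ANGLE"):
            parse_plan_overview(broken)


def test_interrupt_partials_merge_to_segment_time():
    plan = generate_plan(3, n_groups=1, beams_per_group=1, segments_per_beam=2)
    record = simulate_delivery(plan, default_reference_sources(), DATE)
    bid = plan.beams[0].beam_id
    text = write_delivery_log(record)
    seg = record.delivered_beams[0].segments[1]
    part1 = round(seg.beam_on_time * 0.6, 3)
    part2 = round(seg.beam_on_time - part1, 3)
    text += (
        f"[INTERRUPT]\nBEAM = {bid}\nSEGMENT = 2\n"
        f"PARTIAL_TIMES_S = {part1:.3f} {part2:.3f}\n"
    )
    parsed = parse_delivery_log(text)
    (itr,) = parsed.interruptions
    assert itr.partial_times == [part1, part2]
    assert sum(itr.partial_times) == pytest.approx(seg.beam_on_time)


class TestScreenCaptures:
    def test_empty_list_no_warnings(self):
        assert load_screen_captures([]) == ([], [])

    def test_valid_png_loaded(self, tmp_path):
        path = tmp_path / "setup.png"
        Image.new("RGB", (32, 24), "gray").save(path)
        images, warnings = load_screen_captures([path])
        assert len(images) == 1 and images[0].size == (32, 24)
        assert warnings == []

    def test_missing_path_warns_and_continues(self, tmp_path):
        images, warnings = load_screen_captures([tmp_path / "absent.png"])
        assert images == [] and len(warnings) == 1


class TestConfig:
    def test_roundtrip(self):
        tol = ToleranceConfig(reference_sources=default_reference_sources())
        grid = GridSpec(spacing=0.2)
        tol2, grid2 = load_config(write_config(tol, grid))
        assert tol2 == tol and grid2 == grid

    def test_file_roundtrip(self, tmp_path):
        tol = ToleranceConfig(reference_sources=default_reference_sources())
        path = tmp_path / "config.xml"
        path.write_text(write_config(tol, GridSpec()), encoding="utf-8")
        tol2, _ = load_config(path)
        assert tol2 == tol

    def test_unknown_key_rejected(self):
        text = write_config(ToleranceConfig(), GridSpec())
        with pytest.raises(ConfigError, match="couch"):
            load_config(text.replace("<tolerances", "<tolerances couch=\"1\""))

    def test_unknown_element_rejected(self):
        text = write_config(ToleranceConfig(), GridSpec())
        with pytest.raises(ConfigError, match="mystery"):
            load_config(text.replace("</cobaltqa_config>", "<mystery/></cobaltqa_config>"))
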