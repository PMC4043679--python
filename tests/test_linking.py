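"""Frame-to-frame linking, blink-gap re-linking, and duplicate removal."""

import collections

import numpy as np
import pytest

from qdspt.core import (PIXELS, AcquisitionMeta, Localization, TrackSet,
                        convert_units)
from qdspt.linking import (LinkParams, RelinkParams, link_detections,
                           relink_trajectories,
                           remove_cross_channel_duplicates)
from qdspt.simulate import SpeciesSpec, simulate_multispecies

from conftest import make_traj


def detections_from_paths(paths):
    """paths: dict name -> list of (frame, x, y)."""
    dets = []
    for pts in paths.values():
        for f, x, y in pts:
            dets.append(Localization(f, x, y))
    dets.sort(key=lambda d: d.frame)
    return dets


class TestLinkDetections:
    def test_two_separated_particles_yield_two_tracks(self):
        paths = {
            "a": [(f, 0.0 + 0.3 * f, 0.0) for f in range(20)],
            "b": [(f, 30.0, 30.0 + 0.3 * f) for f in range(20)],
        }
        tracks = link_detections(detections_from_paths(paths))
        assert len(tracks) == 2
        assert sorted(len(t) for t in tracks) == [20, 20]

    def test_single_missing_frame_is_bridged(self):
        # oracle: with one detection per frame and one particle, the only
        # consistent assignment is a single track spanning the gap
        pts = [(f, 1.0 + 0.1 * f, 2.0) for f in range(20) if f != 9]
        tracks = link_detections(detections_from_paths({"a": pts}),
                                 LinkParams(link_range=4, max_disp=2.0))
        assert len(tracks) == 1
        assert len(tracks[0]) == 19
        assert 9 not in tracks[0].frames

    def test_jump_beyond_two_pixels_refused(self):
        pts = [(0, 0.0, 0.0), (1, 2.5, 0.0)]
        tracks = link_detections(detections_from_paths({"a": pts}),
                                 LinkParams(link_range=5, max_disp=2.0))
        assert len(tracks) == 2

    def test_empty_input(self):
        assert link_detections([]) == []


def relink_px(trajs, meta, **kw):
    return relink_trajectories(TrackSet(trajs, meta), RelinkParams(**kw))


class TestRelink:
    def test_immobile_split_track_is_merged(self, meta):
        xy = np.tile([5.0, 5.0], (30, 1))
        a = make_traj("a", xy, frames=np.arange(30))
        b = make_traj("b", xy, frames=np.arange(40, 70))
        out = relink_px([a, b], meta, min_len=10)
        assert len(out) == 1
        merged = out.trajectories[0]
        assert len(merged) == 60
        assert merged.merged_from == ["a", "b"]
        assert 35 not in merged.frames          # no interpolation

    def test_gap_of_150_frames_not_merged(self, meta):
        xy = np.tile([5.0, 5.0], (60, 1))
        a = make_traj("a", xy, frames=np.arange(60))
        b = make_traj("b", xy, frames=np.arange(210, 270))
        out = relink_px([a, b], meta, min_len=50)
        assert sorted(t.id for t in out) == ["a", "b"]

    @pytest.mark.parametrize("sq_dist,merged", [(0.5, True), (1.5, False)])
    def test_spatial_criterion_is_point_one_per_gap_frame(
            self, meta, sq_dist, merged):
        # gap of 10 frames -> threshold 0.1 x 10 = 1 px^2
        a = make_traj("a", np.tile([0.0, 0.0], (60, 1)),
                      frames=np.arange(60))
        start = np.array([np.sqrt(sq_dist), 0.0])
        b = make_traj("b", np.tile(start, (60, 1)),
                      frames=np.arange(69, 129))
        out = relink_px([a, b], meta, min_len=10)
        assert (len(out) == 1) is merged

    def test_time_overlapping_tracks_never_merged(self, meta):
        xy = np.tile([1.0, 1.0], (60, 1))
        a = make_traj("a", xy, frames=np.arange(60))
        b = make_traj("b", xy, frames=np.arange(30, 90))
        out = relink_px([a, b], meta, min_len=10)
        assert len(out) == 2

    def test_chain_of_fragments_merges_in_order(self, meta):
        frags = [
            make_traj(f"f{k}", np.tile([2.0, 2.0], (30, 1)),
                      frames=np.arange(k * 40, k * 40 + 30))
            for k in range(4)
        ]
        out = relink_px(frags, meta, min_len=10)
        assert len(out) == 1
        assert out.trajectories[0].merged_from == ["f0", "f1", "f2", "f3"]

    def test_positions_conserved_as_multiset(self, meta):
        rng = np.random.default_rng(5)
        frags = []
        start = 0
        for k in range(6):
            n = int(rng.integers(20, 40))
            xy = rng.normal(3.0, 0.05, size=(n, 2))
            frags.append(make_traj(f"f{k}", xy,
                                   frames=np.arange(start, start + n)))
            start += n + int(rng.integers(2, 20))
        before = collections.Counter(
            (int(f), float(x), float(y))
            for t in frags for f, (x, y) in zip(t.frames, t.xy))
        out = relink_px(frags, meta, min_len=1)
        after = collections.Counter(
            (int(f), float(x), float(y))
            for t in out for f, (x, y) in zip(t.frames, t.xy))
        assert before == after

    def test_relink_is_idempotent(self, meta):
        rng = np.random.default_rng(11)
        frags = []
        start = 0
        for k in range(8):
            n = int(rng.integers(20, 40))
            xy = rng.normal(k % 3 * 20.0, 0.1, size=(n, 2))
            frags.append(make_traj(f"f{k}", xy,
                                   frames=np.arange(start, start + n)))
            start += n + int(rng.integers(2, 30))
        once = relink_px(frags, meta, min_len=1)
        twice = relink_trajectories(once, RelinkParams(min_len=1))
        assert [t.id for t in twice] == [t.id for t in once]
        for a, b in zip(once, twice):
            assert np.array_equal(a.frames, b.frames)

    def test_min_len_keeps_only_tracks_longer_than_50_steps(self, meta):
        a = make_traj("short", np.zeros((51, 2)), frames=np.arange(51))
        b = make_traj("long", np.ones((52, 2)) * 30,
                      frames=np.arange(52))
        out = relink_px([a, b], meta)      # defaults: min_len=50
        assert [t.id for t in out] == ["long"]   # 51 displacements > 50


class TestRelinkGroundTruth:
    def test_blink_fragments_rejoined_without_cross_merges(self, meta):
        """Near-immobile blinking particles, gaps capped below the 100-frame
        limit, particles far apart: the coincidence search restores >=90% of
        the true fragment chain and never bridges particles."""
        spec = SpeciesSpec(name="QD655", D_components=((0.0005, 1.0),),
                           localization_sigma=0.020,
                           blink_off_rate=1 / 150, blink_on_rate=1 / 20,
                           n_particles=40)
        tracksets, truth = simulate_multispecies(
            [spec], meta, n_frames=1200, seed=3, max_blink_gap=90,
            spacing_um=2.0)
        ts_px = convert_units(tracksets["QD655"], PIXELS)
        merged = relink_trajectories(ts_px, RelinkParams(min_len=1))

        frag2part = dict(zip(truth.fragment_id, truth.particle_id))
        chains = collections.defaultdict(list)
        for row in truth.itertuples():
            chains[row.particle_id].append(row.fragment_id)
        true_pairs = {
            pair for frs in chains.values() for pair in zip(frs, frs[1:])}
        recovered = set()
        for t in merged:
            sources = t.merged_from or [t.id]
            assert len({frag2part[s] for s in sources}) == 1, \
                "cross-particle merge"
            recovered.update(zip(sources, sources[1:]))
        assert len(true_pairs & recovered) / len(true_pairs) >= 0.90


class TestDedupe:
    def _sets(self, meta, offset):
        xy = np.cumsum(np.full((60, 2), 0.05), axis=0) + 10.0
        a = TrackSet([make_traj("a", xy, channel="QD605")], meta)
        b = TrackSet([make_traj("b", xy + offset, channel="QD655")], meta)
        return [a, b]

    def test_identical_duplicate_removed_from_lower_priority(self, meta):
        out = remove_cross_channel_duplicates(self._sets(meta, 0.0))
        assert len(out[0]) == 1 and len(out[1]) == 0

    def test_distant_tracks_both_kept(self, meta):
        out = remove_cross_channel_duplicates(self._sets(meta, 10.0))
        assert len(out[0]) == 1 and len(out[1]) == 1

    def test_overlap_fraction_threshold(self, meta):
        # 90% of shared frames within radius, min_overlap_fraction=0.8
        xy = np.tile([5.0, 5.0], (60, 1))
        other = xy.copy()
        other[:6] += 3.0      # 10% of frames displaced beyond the radius
        a = TrackSet([make_traj("a", xy, channel="c1")], meta)
        b = TrackSet([make_traj("b", other, channel="c2")], meta)
        out = remove_cross_channel_duplicates([a, b], radius=0.5,
                                              min_overlap_fraction=0.8)
        assert len(out[1]) == 0
        # brute-force oracle on the same pair
        within = np.mean(np.linalg.norm(xy - other, axis=1) <= 0.5)
        assert within >= 0.8

    def test_single_channel_passthrough(self, meta):
        sets = self._sets(meta, 0.0)[:1]
        assert remove_cross_channel_duplicates(sets) == sets
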