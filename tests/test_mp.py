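import numpy as np
import pytest

from spindlemp.dictionary import AtomParams, build_dictionary, gabor_waveform
from spindlemp.mp import (
    Book,
    FittedAtom,
    best_match,
    decompose,
    read_book,
    reconstruct,
    write_book,
)

import oracle_utils

FS = 256.0


def grid_atom_params(dictionary, scale_idx, u_idx, f_idx, phi=0.0):
    g = dictionary.grids[scale_idx]
    return AtomParams(u=float(g.u_values[u_idx]), s=g.s,
                      f=float(g.f_values[f_idx]), phi=phi)


class TestBestMatch:
    def test_exact_atom_self_match(self, small_dictionary):
        params = grid_atom_params(small_dictionary, 1, 8, 30, phi=0.4)
        sig = 5.0 * gabor_waveform(params, FS, small_dictionary.n_samples)
        atom = best_match(sig, small_dictionary)
        assert atom.params.u == pytest.approx(params.u)
        assert atom.params.s == pytest.approx(params.s)
        assert atom.params.f == pytest.approx(params.f)
        assert atom.coeff == pytest.approx(5.0, abs=1e-6)

    def test_matches_exhaustive_scan_on_noise(self, small_dictionary, rng):
        sig = rng.standard_normal(small_dictionary.n_samples)
        atom = best_match(sig, small_dictionary)
        energy, u, f, s = oracle_utils.scan_dictionary(sig, small_dictionary)
        assert atom.params.u == pytest.approx(u, abs=1e-12)
        assert atom.params.f == pytest.approx(f, abs=1e-12)
        assert atom.params.s == pytest.approx(s, abs=1e-12)
        assert atom.coeff**2 == pytest.approx(energy, rel=1e-9)

    def test_phase_recovered_analytically(self, small_dictionary):
        params = grid_atom_params(small_dictionary, 2, 5, 40, phi=1.0)
        sig = 3.0 * gabor_waveform(params, FS, small_dictionary.n_samples)
        atom = best_match(sig, small_dictionary)
        assert atom.params.phi == pytest.approx(1.0, abs=1e-3)

    def test_zero_residual_flagged_degenerate(self, small_dictionary):
        atom = best_match(np.zeros(small_dictionary.n_samples), small_dictionary)
        assert atom.degenerate
        assert atom.coeff == 0.0


class TestDecompose:
    def test_exact_atom_captured_in_one_iteration(self, small_dictionary):
        params = grid_atom_params(small_dictionary, 1, 10, 25, phi=2.0)
        sig = 7.0 * gabor_waveform(params, FS, small_dictionary.n_samples)
        book = decompose(sig, small_dictionary, M=1)
        assert book.residual_energy / book.signal_energy < 1e-10

    @pytest.mark.parametrize("seed,m", [(0, 10), (1, 25)])
    def test_energy_conservation(self, small_dictionary, seed, m):
        rng = np.random.default_rng(seed)
        sig = rng.standard_normal(small_dictionary.n_samples)
        book = decompose(sig, small_dictionary, M=m)
        captured = sum(a.coeff**2 for a in book.atoms)
        err = abs(book.signal_energy - captured - book.residual_energy)
        assert err / book.signal_energy < 1e-6

    def test_two_atom_recovery(self, small_dictionary):
        n = small_dictionary.n_samples
        p1 = grid_atom_params(small_dictionary, 1, 4, 30, phi=0.3)
        g2grid = small_dictionary.grids[1]
        # second atom well separated in time
        u2_idx = int(np.argmin(np.abs(g2grid.u_values - (p1.u + 1.2))))
        p2 = AtomParams(u=float(g2grid.u_values[u2_idx]), s=g2grid.s,
                        f=float(g2grid.f_values[50]), phi=1.1)
        sig = 10.0 * gabor_waveform(p1, FS, n) + 5.0 * gabor_waveform(p2, FS, n)
        book = decompose(sig, small_dictionary, M=2)
        coeffs = sorted((a.coeff for a in book.atoms), reverse=True)
        assert coeffs[0] == pytest.approx(10.0, rel=0.02)
        assert coeffs[1] == pytest.approx(5.0, rel=0.02)

    def test_prefix_stability(self, small_dictionary, rng):
        sig = rng.standard_normal(small_dictionary.n_samples)
        short = decompose(sig, small_dictionary, M=4)
        long = decompose(sig, small_dictionary, M=8)
        for a, b in zip(short.atoms, long.atoms[:4]):
            assert a.params == b.params
            assert a.coeff == b.coeff

    def test_oracle_equivalence_atom_for_atom(self, small_dictionary, rng):
        # greedy selection equals exhaustive search at every iteration
        sig = rng.standard_normal(small_dictionary.n_samples)
        book = decompose(sig, small_dictionary, M=3)
        residual = sig.copy()
        for atom in book.atoms:
            energy, u, f, s = oracle_utils.scan_dictionary(
                residual, small_dictionary
            )
            assert atom.params.u == pytest.approx(u, abs=1e-12)
            assert atom.params.f == pytest.approx(f, abs=1e-12)
            assert atom.params.s == pytest.approx(s, abs=1e-12)
            assert atom.coeff**2 == pytest.approx(energy, rel=1e-9)
            residual -= atom.coeff * gabor_waveform(
                atom.params, FS, small_dictionary.n_samples
            )

    def test_residual_energy_strictly_decreasing(self, small_dictionary, rng):
        sig = rng.standard_normal(small_dictionary.n_samples)
        books = [decompose(sig, small_dictionary, M=m) for m in (1, 3, 6)]
        energies = [b.residual_energy for b in books]
        assert energies[0] > energies[1] > energies[2]

    def test_rejects_non_finite_signal(self, small_dictionary):
        sig = np.zeros(small_dictionary.n_samples)
        sig[10] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            decompose(sig, small_dictionary, M=1)

    def test_rejects_wrong_length(self, small_dictionary):
        with pytest.raises(ValueError):
            decompose(np.zeros(100), small_dictionary, M=1)


class TestReconstruct:
    def test_zero_atoms_gives_zero_signal(self, small_dictionary, rng):
        sig = rng.standard_normal(small_dictionary.n_samples)
        book = decompose(sig, small_dictionary, M=2)
        assert not np.any(reconstruct(book, 0))

    def test_noiseless_on_grid_input_reconstructed(self, small_dictionary):
        params = grid_atom_params(small_dictionary, 2, 7, 33, phi=0.9)
        sig = 4.0 * gabor_waveform(params, FS, small_dictionary.n_samples)
        book = decompose(sig, small_dictionary, M=1)
        rec = reconstruct(book)
        assert np.linalg.norm(sig - rec) / np.linalg.norm(sig) < 1e-5

    def test_residual_matches_direct_subtraction(self, small_dictionary, rng):
        sig = rng.standard_normal(small_dictionary.n_samples)
        book = decompose(sig, small_dictionary, M=5)
        residual = sig - reconstruct(book)
        assert float(residual @ residual) == pytest.approx(
            book.residual_energy, rel=1e-6
        )


class TestBookIO:
    def make_book(self):
        atoms = [
            FittedAtom(AtomParams(u=1.25, s=0.5, f=13.0, phi=0.7),
                       coeff=12.5, iteration=0),
            FittedAtom(AtomParams(u=0.5, s=0.125, f=2.0, phi=-2.1),
                       coeff=3.25, iteration=1),
        ]
        return Book(atoms=atoms, fs=FS, epoch_start=40.0, epoch_length=2.0,
                    signal_energy=200.0, residual_energy=32.1875, epsilon=0.2)

    def test_round_trip_exact(self, tmp_path):
        book = self.make_book()
        path = tmp_path / "book.csv"
        write_book(book, path)
        loaded = read_book(path)
        assert loaded.fs == book.fs
        assert loaded.epoch_start == book.epoch_start
        assert loaded.signal_energy == book.signal_energy
        assert loaded.residual_energy == book.residual_energy
        assert loaded.epsilon == book.epsilon
        for a, b in zip(loaded.atoms, book.atoms):
            assert a.params == b.params
            assert abs(a.coeff - b.coeff) < 1e-12
            assert a.iteration == b.iteration

    def test_empty_book_round_trip(self, tmp_path):
        book = Book(atoms=[], fs=FS, epoch_start=0.0, epoch_length=2.0,
                    signal_energy=0.0, residual_energy=0.0)
        path = tmp_path / "empty.csv"
        write_book(book, path)
        assert read_book(path).atoms == []

    def test_hand_written_file(self, tmp_path):
        path = tmp_path / "hand.csv"
        path.write_text(
            "# fs=128.0\n# epoch_start=20.0\n# epoch_length=4.0\n"
            "# signal_energy=50.0\n# residual_energy=5.0\n# epsilon=0.1\n"
            "# M=2\n"
            "iteration,u,s,f,phi,coeff,energy\n"
            "0,1.0,0.5,12.0,0.25,6.0,36.0\n"
            "1,2.5,0.25,14.0,-0.5,3.0,9.0\n"
        )
        book = read_book(path)
        assert book.fs == 128.0
        assert len(book.atoms) == 2
        assert book.atoms[1].params.u == 2.5
        assert book.atoms[1].coeff == 3.0

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "# fs=128.0\n# epoch_start=0.0\n# epoch_length=4.0\n"
            "# signal_energy=1.0\n# residual_energy=1.0\n"
            "iteration,u,s,f,phi,coeff,energy\n"
            "0,1.0,0.5,12.0,0.25,6.0,36.0\n"
            "1,oops,0.25,14.0,-0.5,3.0,9.0\n"
        )
        with pytest.raises(ValueError, match="line 8"):
            read_book(path)
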