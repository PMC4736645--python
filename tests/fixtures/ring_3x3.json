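{"format": "pglattice-world", "version": 1, "height": 3, "width": 3, "t": 0, "occupancy": [[1, 1, 1], [1, 0, 1], [1, 1, 1]], "production": [[6.0, 6.0, 6.0], [6.0, 0.0, 6.0], [6.0, 6.0, 6.0]], "strain_label": [[0, 0, 0], [0, -1, 0], [0, 0, 0]], "params": {"b": 10.0, "c": 4.5, "k_death": 0.2, "k_move": 0.02, "mu": 0.05, "delta": 0.1, "p_max": 10.0, "width": 3, "height": 3, "boundary": "toroidal", "altruism": "weak", "strong_share": "split8", "seed": 0}}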