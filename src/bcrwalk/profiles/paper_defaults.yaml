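d_min: 10.0
half_width: 0.39269908169872414
grid: 210
levels:
- 100
- 99
- 95
- 90
- 80
- 70
- 60
- 50
- 40
- 30
- 20
- 10
radii:
- 1
- 2
- 3
- 4
- 5
- 6
- 7
- 8
- 9
- 10
- 11
- 12
- 13
- 14
- 15
- 16
- 17
- 18
- 19
- 20
- 21
- 22
- 23
- 24
- 25
- 26
- 27
- 28
- 29
- 30
- 31
- 32
- 33
- 34
- 35
- 36
- 37
- 38
- 39
- 40
- 41
- 42
- 43
- 44
- 45
- 46
- 47
- 48
- 49
- 50
- 51
- 52
- 53
- 54
- 55
- 56
- 57
- 58
- 59
- 60
- 61
- 62
- 63
- 64
- 65
- 66
- 67
- 68
- 69
- 70
- 71
- 72
- 73
- 74
- 75
- 76
- 77
- 78
- 79
- 80
- 81
- 82
- 83
- 84
- 85
- 86
- 87
- 88
- 89
- 90
- 91
- 92
- 93
- 94
- 95
- 96
- 97
- 98
- 99
- 100
pixel_size: 1.0
sight: 200.0
n_transects: 100
sights:
- 50
- 100
- 200
- 400
- 500
- 1000
speed_multipliers:
- 0.25
- 0.5
- 1.0
- 2.0
respawn_ticks: 10000
rotation_radius: 500.0
clock_divisor: 10
alpha_radius: 60.0
min_void_area: 100.0
p_cut: 0.05
n_sim: 1000
seed: 0
placement_seed: 0
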