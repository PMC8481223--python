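n,alpha,critical_value
4,0.1,167.89
4,0.05,186.51
4,0.01,220.97
4,0.001,247.2
5,0.1,168.69
5,0.05,183.42
5,0.01,212.02
5,0.001,244.92
6,0.1,166.14
6,0.05,180.61
6,0.01,206.8
6,0.001,236.25
7,0.1,164.99
7,0.05,177.87
7,0.01,202.44
7,0.001,229.15
8,0.1,163.58
8,0.05,175.77
8,0.01,198.45
8,0.001,224.3
9,0.1,162.44
9,0.05,173.76
9,0.01,195.42
9,0.001,219.93
10,0.1,161.27
10,0.05,171.92
10,0.01,192.13
10,0.001,215.32
11,0.1,160.16
11,0.05,170.34
11,0.01,189.91
11,0.001,211.96
12,0.1,159.33
12,0.05,169.09
12,0.01,187.79
12,0.001,209.13
13,0.1,158.56
13,0.05,167.93
13,0.01,185.72
13,0.001,205.62
14,0.1,157.77
14,0.05,166.8
14,0.01,183.89
14,0.001,203.19
15,0.1,157.06
15,0.05,165.78
15,0.01,182.37
15,0.001,200.88
16,0.1,156.36
16,0.05,164.75
16,0.01,180.86
16,0.001,199.36
17,0.1,155.85
17,0.05,164.02
17,0.01,179.58
17,0.001,197.28
18,0.1,155.33
18,0.05,163.24
18,0.01,178.25
18,0.001,195.29
19,0.1,154.84
19,0.05,162.51
19,0.01,177.07
19,0.001,193.51
20,0.1,154.32
20,0.05,161.8
20,0.01,176.11
20,0.001,192.38
21,0.1,153.96
21,0.05,161.23
21,0.01,175.15
21,0.001,190.74
22,0.1,153.42
22,0.05,160.52
22,0.01,174.05
22,0.001,189.76
23,0.1,152.97
23,0.05,159.93
23,0.01,173.18
23,0.001,188.22
24,0.1,152.71
24,0.05,159.52
24,0.01,172.43
24,0.001,187.6
25,0.1,152.37
25,0.05,158.96
25,0.01,171.61
25,0.001,185.92
26,0.1,152.01
26,0.05,158.57
26,0.01,170.98
26,0.001,184.99
27,0.1,151.65
27,0.05,158.08
27,0.01,170.25
27,0.001,184.34
28,0.1,151.36
28,0.05,157.6
28,0.01,169.59
28,0.001,183.25
29,0.1,151.11
29,0.05,157.27
29,0.01,169.06
29,0.001,182.29
30,0.1,150.84
30,0.05,156.86
30,0.01,168.38
30,0.001,181.0
31,0.1,150.54
31,0.05,156.5
31,0.01,167.78
31,0.001,180.91
32,0.1,150.27
32,0.05,156.12
32,0.01,167.36
32,0.001,179.9
33,0.1,150.05
33,0.05,155.82
33,0.01,166.76
33,0.001,179.31
34,0.1,149.83
34,0.05,155.5
34,0.01,166.27
34,0.001,178.56
35,0.1,149.58
35,0.05,155.25
35,0.01,165.85
35,0.001,177.86
36,0.1,149.34
36,0.05,154.83
36,0.01,165.34
36,0.001,177.12
37,0.1,149.15
37,0.05,154.58
37,0.01,165.01
37,0.001,176.92
38,0.1,149.02
38,0.05,154.38
38,0.01,164.55
38,0.001,176.1
39,0.1,148.77
39,0.05,154.05
39,0.01,164.08
39,0.001,175.4
40,0.1,148.58
40,0.05,153.84
40,0.01,163.78
40,0.001,175.09
41,0.1,148.45
41,0.05,153.64
41,0.01,163.43
41,0.001,174.57
42,0.1,148.24
42,0.05,153.36
42,0.01,162.98
42,0.001,174.05
43,0.1,148.05
43,0.05,153.11
43,0.01,162.54
43,0.001,173.56
44,0.1,147.93
44,0.05,152.89
44,0.01,162.3
44,0.001,172.95
45,0.1,147.78
45,0.05,152.67
45,0.01,162.08
45,0.001,172.64
46,0.1,147.6
46,0.05,152.47
46,0.01,161.7
46,0.001,172.11
47,0.1,147.46
47,0.05,152.25
47,0.01,161.4
47,0.001,171.98
48,0.1,147.26
48,0.05,152.01
48,0.01,161.0
48,0.001,171.35
49,0.1,147.17
49,0.05,151.87
49,0.01,160.85
49,0.001,170.69
50,0.1,147.06
50,0.05,151.74
50,0.01,160.63
50,0.001,170.68
51,0.1,146.92
51,0.05,151.54
51,0.01,160.34
51,0.001,170.39
52,0.1,146.74
52,0.05,151.3
52,0.01,159.89
52,0.001,169.68
53,0.1,146.65
53,0.05,151.18
53,0.01,159.72
53,0.001,169.32
54,0.1,146.57
54,0.05,151.04
54,0.01,159.57
54,0.001,169.23
55,0.1,146.42
55,0.05,150.88
55,0.01,159.32
55,0.001,168.76
56,0.1,146.31
56,0.05,150.72
56,0.01,159.11
56,0.001,168.48
57,0.1,146.2
57,0.05,150.56
57,0.01,158.88
57,0.001,168.35
58,0.1,146.12
58,0.05,150.44
58,0.01,158.59
58,0.001,167.83
59,0.1,145.97
59,0.05,150.26
59,0.01,158.42
59,0.001,167.49
60,0.1,145.86
60,0.05,150.13
60,0.01,158.12
60,0.001,167.24
65,0.1,145.41
65,0.05,149.44
65,0.01,157.25
65,0.001,165.95
70,0.1,144.94
70,0.05,148.85
70,0.01,156.31
70,0.001,164.81
75,0.1,144.58
75,0.05,148.34
75,0.01,155.46
75,0.001,163.48
80,0.1,144.19
80,0.05,147.85
80,0.01,154.79
80,0.001,162.66
90,0.1,143.51
90,0.05,146.95
90,0.01,153.44
90,0.001,160.92
100,0.1,143.0
100,0.05,146.23
100,0.01,152.42
100,0.001,159.49
125,0.1,141.99
125,0.05,144.94
125,0.01,150.4
125,0.001,156.86
150,0.1,141.18
150,0.05,143.84
150,0.01,148.79
150,0.001,154.55
200,0.1,140.07
200,0.05,142.35
200,0.01,146.67
200,0.001,151.51
300,0.1,138.75
300,0.05,140.63
300,0.01,144.17
300,0.001,148.18
500,0.1,137.32
500,0.05,138.77
500,0.01,141.52
500,0.001,144.72
1000,0.1,135.91
1000,0.05,136.93
1000,0.01,138.82
1000,0.001,140.9
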