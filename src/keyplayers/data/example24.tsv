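# 24-node example network (synthetic reconstruction).
# Edge list rebuilt by constraint search so that every published fact about
# the network holds: hub degrees 7/6/5/4 for nodes 2/9/16/21, distance 5
# between nodes 2 and 9, both group-metric tables, and the exhaustive-search
# optima for group sizes 2, 5, and 6.  validate_fixture() re-checks all of
# these facts.
1	2
2	3
2	4
2	5
2	6
2	7
2	8
5	11
9	12
9	13
9	14
9	15
9	16
9	21
10	11
11	22
14	17
16	17
16	18
16	19
16	20
21	22
21	23
21	24
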