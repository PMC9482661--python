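>PLANTED
A [ 93.1818 2.27273 2.27273 2.27273 2.27273 93.1818 2.27273 2.27273 ]
C [ 2.27273 93.1818 2.27273 2.27273 93.1818 2.27273 2.27273 2.27273 ]
G [ 2.27273 2.27273 93.1818 2.27273 2.27273 2.27273 93.1818 2.27273 ]
T [ 2.27273 2.27273 2.27273 93.1818 2.27273 2.27273 2.27273 93.1818 ]
>DECOY1
A [ 47.561 30.6818 32.2222 32.4561 20.8333 44.5946 36.4583 13.0952 ]
C [ 6.09756 17.0455 14.4444 32.4561 32.5 4.05405 21.875 41.6667 ]
G [ 8.53659 37.5 7.77778 18.4211 29.1667 20.2703 15.625 15.4762 ]
T [ 37.8049 14.7727 45.5556 16.6667 17.5 31.0811 26.0417 29.7619 ]
>DECOY2
A [ 23.4694 50 36.4583 37.5 25.4098 28.125 20.2703 43.617 ]
C [ 21.4286 13.4146 36.4583 10.2273 30.3279 28.125 9.45946 3.19149 ]
G [ 19.3878 3.65854 7.29167 26.1364 33.6066 21.875 47.2973 41.4894 ]
T [ 35.7143 32.9268 19.7917 26.1364 10.6557 21.875 22.973 11.7021 ]
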